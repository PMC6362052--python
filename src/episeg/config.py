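"""Experiment configuration: the two-arm study description.

The default ("desk") configuration shrinks the acquisition (48x48x12 matrix,
120 multishot volumes, 8 subjects per arm) while preserving every structural
parameter of the full protocols; ``full_config()`` restores the full-size
acquisition (96x96x16, 900/1800 volumes).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .synth import NetworkSpec, Phantom, SequenceParams, ms_protocol, ss_protocol

__all__ = ["ArmConfig", "ExperimentConfig", "default_config", "full_config",
           "build_network_spec"]


@dataclass
class ArmConfig:
    seq: SequenceParams
    spike_rate: float = 0.0


@dataclass
class ExperimentConfig:
    # phantom / anatomy
    shape: tuple[int, int, int] = (48, 48, 12)
    n_cortical: int = 8
    n_subcortical: int = 12
    fov_mm: tuple[float, float, float] = (35.0, 35.0, 16.0)
    pe_axis: int = 1
    # field map / distortion physics
    peak_hz: float = 200.0
    width_mm: float = 2.0
    ventral_gradient_hz: float = 600.0    # shim-failure field toward skull base
    fieldmap_jitter: float = 0.1          # per-subject fractional peak jitter
    kappa: float = 1.5                    # TE-driven dropout strength
    kappa_readout: float = 15.0            # echo-train dephasing strength
    # networks
    network_amplitude: float = 0.02
    network_amplitude_deep: float = 0.03   # deep nuclei fluctuate strongly
    amplitude_jitter: float = 0.0          # between-subject amplitude spread
    band_hz: tuple[float, float] = (0.01, 0.1)
    cross_network_correlation: float = 0.1
    session_noise_fraction: float = 0.5   # share of regional noise that is
                                          # session- (not subject-) specific
    n_cortical_networks: int = 3
    n_subcortical_networks: int = 4
    pairs_per_cortical_network: int = 2
    pairs_per_subcortical_network: int = 3
    # arms
    ms: ArmConfig = field(default_factory=lambda: ArmConfig(
        seq=ms_protocol(matrix=(48, 48, 12), n_rep=120,
                        sigma_thermal=0.3, shot_instability=0.002,
                        sigma_regional=0.22),
        spike_rate=0.03))
    ss: ArmConfig = field(default_factory=lambda: ArmConfig(
        seq=ss_protocol(matrix=(48, 48, 12), n_rep=240,
                        sigma_thermal=0.3, shot_instability=0.0,
                        sigma_regional=0.352),
        spike_rate=0.01))
    n_subjects: int = 8
    # analysis
    n_ica_subject: int = 12
    d_ica_group: int = 8
    run_ica: bool = True
    n_perm: int = 100
    tfce_E: float = 0.5
    tfce_H: float = 2.0
    z0: float = 2.3
    alpha: float = 0.05
    power: float = 0.8
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        for arm in ("ms", "ss"):
            if arm in d and isinstance(d[arm], dict):
                seq = d[arm]["seq"]
                if isinstance(seq, dict):
                    seq = {k: tuple(v) if isinstance(v, list) else v
                           for k, v in seq.items()}
                    seq = SequenceParams(**seq)
                d[arm] = ArmConfig(seq=seq,
                                   spike_rate=d[arm].get("spike_rate", 0.0))
        for key in ("shape", "fov_mm", "band_hz"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict(), default=str)),
                           fh, sort_keys=True)


def default_config(**overrides) -> ExperimentConfig:
    """The desk-scale two-arm study configuration."""
    cfg = ExperimentConfig()
    for k, v in overrides.items():
        if not hasattr(cfg, k):
            raise AttributeError(f"unknown config field {k!r}")
        setattr(cfg, k, v)
    return cfg


def full_config(**overrides) -> ExperimentConfig:
    """The full-size protocols (96x96x16, 900/1800 volumes, 26 subjects)."""
    base = dict(
        shape=(96, 96, 16),
        ms=ArmConfig(seq=ms_protocol(sigma_thermal=2.0, shot_instability=0.002),
                     spike_rate=0.03),
        ss=ArmConfig(seq=ss_protocol(sigma_thermal=2.0), spike_rate=0.01),
        n_subjects=26, n_ica_subject=70, d_ica_group=30, n_perm=500,
    )
    base.update(overrides)
    return default_config(**base)


def build_network_spec(phantom: Phantom, cfg: ExperimentConfig) -> NetworkSpec:
    """Plant networks on the phantom.

    Cortical networks pair consecutive left/right cortical parcels;
    subcortical ("deep") networks take the subcortical parcel pairs closest
    to the air cavities, so that the arm contrast concentrates where
    susceptibility artifacts live — mirroring amygdala/hypothalamus-type
    networks.
    """
    t = phantom.parcels
    cav_cents = [phantom.parcel_centroid(int(pid))
                 for pid in phantom.parcel_ids("air")]

    def _pairs(klass):
        sel = t[t.klass == klass]
        base_names = sorted({n.rsplit("-", 1)[0] for n in sel.name})
        pairs = []
        for bn in base_names:
            ids = tuple(int(i) for i in sel[sel.name.str.startswith(bn + "-")].id)
            cents = [phantom.parcel_centroid(i) for i in ids]
            d = min(np.linalg.norm(c - cc) for c in cents for cc in cav_cents)
            pairs.append((bn, ids, d))
        return pairs

    nets = []
    cort = _pairs("cortical")
    # cortical networks: bilateral pairs farthest from the cavities (dorsal),
    # two parcel pairs per network (an RSN spans several regions)
    cort.sort(key=lambda p: -p[2])
    kc = cfg.pairs_per_cortical_network
    for i in range(min(cfg.n_cortical_networks, len(cort) // kc)):
        members = sum((cort[kc * i + j][1] for j in range(kc)), ())
        nets.append((f"cortical-net-{i + 1}", members, cfg.network_amplitude))
    sub = _pairs("subcortical")
    sub.sort(key=lambda p: p[2])     # closest to cavities first
    ks = cfg.pairs_per_subcortical_network
    for i in range(min(cfg.n_subcortical_networks, len(sub) // ks)):
        members = sum((sub[ks * i + j][1] for j in range(ks)), ())
        nets.append((f"deep-net-{i + 1}", members, cfg.network_amplitude_deep))
    return NetworkSpec(networks=nets, band_hz=cfg.band_hz,
                       cross_network_correlation=cfg.cross_network_correlation)
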