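"""Synthetic EPI acquisition model for segmented vs single-shot resting-state fMRI.

This module builds the digital subject and the acquisition physics used by the
rest of the pipeline:

* a phantom "rat brain" — an ellipsoidal label volume with cortical parcels on
  the dorsal shell, subcortical parcels in the ventral interior, and air
  cavities placed ventro-laterally (the aural/nasal cavity analogue);
* a B0 off-resonance field map concentrated around the air cavities, which is
  where susceptibility mismatch is largest;
* the echo-planar readout model: per-pixel phase-encode bandwidth set by the
  echo train length, off-resonance voxel displacement along the phase-encode
  axis, and through-gradient signal dropout;
* seeded resting-state network time courses and the full 4D acquisition with
  steady-state (Ernst) scaling, inter-shot instability, motion spikes and
  thermal noise.

Segmentation (multishot EPI) enters the physics only through the echo train
length: with NSHOTS shots and parallel factor PPI the echo train is
n_pe/(NSHOTS*PPI) lines, so per-pixel PE bandwidth — and hence geometric
distortion — scales as 1/NSHOTS.  The price of segmentation is a slower
volume rate (tr_vol = tr_shot * n_shots) and sensitivity to inter-shot
instability, modelled as volume-level multiplicative noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Phantom",
    "FieldMap",
    "SequenceParams",
    "NetworkSpec",
    "Volume4D",
    "DisplacementField",
    "make_phantom",
    "make_fieldmap",
    "pe_bandwidth_per_pixel",
    "pe_displacement",
    "dropout_map",
    "ernst_signal",
    "simulate_network_timecourses",
    "acquire_series",
    "acquisition_time_min",
    "make_confounds",
    "ms_protocol",
    "ss_protocol",
    "derive_seed",
]


def derive_seed(master: int, *keys: int) -> int:
    """Deterministic child seed from a master seed and integer keys (< 2**31)."""
    ss = np.random.SeedSequence([int(master), *[int(k) for k in keys]])
    return int(ss.generate_state(1)[0] % (2**31))


# --------------------------------------------------------------------------- #
# domain types
# --------------------------------------------------------------------------- #

@dataclass
class Phantom:
    """Digital subject: label volume + baseline signal intensity map.

    labels: 0 = background, 1..K = parcels (see ``parcels`` table for class).
    baseline is zero exactly on background and air-cavity voxels.
    """

    labels: np.ndarray
    baseline: np.ndarray
    voxel_size: tuple[float, float, float]
    pe_axis: int = 1
    parcels: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.labels.shape != self.baseline.shape:
            raise ValueError("labels and baseline must share a shape")
        if self.pe_axis not in (0, 1, 2):
            raise ValueError("pe_axis must be 0, 1 or 2")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape

    def parcel_ids(self, klass: str | None = None) -> np.ndarray:
        t = self.parcels
        if klass is not None:
            t = t[t["klass"] == klass]
        return t["id"].to_numpy()

    @property
    def brain_mask(self) -> np.ndarray:
        """Voxels belonging to tissue parcels (cortical or subcortical)."""
        ids = set(self.parcel_ids("cortical")) | set(self.parcel_ids("subcortical"))
        return np.isin(self.labels, sorted(ids))

    def parcel_centroid(self, pid: int) -> np.ndarray:
        idx = np.argwhere(self.labels == pid)
        if idx.size == 0:
            raise ValueError(f"parcel {pid} absent from labels")
        return idx.mean(axis=0)


@dataclass
class FieldMap:
    """Off-resonance map Δf in Hz per voxel."""

    delta_f: np.ndarray
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.delta_f)):
            raise ValueError("field map must be finite everywhere")


@dataclass
class DisplacementField:
    """Signed voxel displacement along the phase-encode axis."""

    shift_vox: np.ndarray
    pe_axis: int


@dataclass
class SequenceParams:
    """Complete EPI protocol description.

    tr_shot_ms is the per-excitation repetition time; the effective volume TR
    is ``tr_shot_ms * n_shots`` (segments of one volume are acquired on
    successive excitations).
    """

    tr_shot_ms: float
    n_shots: int
    te_ms: float
    flip_deg: float
    matrix: tuple[int, int, int]        # (n_ro, n_pe, n_slices)
    fov_mm: tuple[float, float, float]
    bw_hz: float
    ppi: int
    n_rep: int
    echo_spacing_ms: float = 0.5
    t1_ms: float = 1400.0
    t2s_ms: float = 25.0
    sigma_thermal: float = 0.0
    shot_instability: float = 0.0
    sigma_regional: float = 0.0     # parcel-coherent structured-noise SD (a.u.)
    field_instability: float = 0.0  # fractional temporal B0 fluctuation SD

    def __post_init__(self) -> None:
        if self.n_shots < 1 or self.ppi < 1:
            raise ValueError("n_shots and ppi must be >= 1")
        for name in ("tr_shot_ms", "te_ms", "echo_spacing_ms", "t1_ms", "t2s_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        n_pe = self.matrix[1]
        if n_pe % (self.n_shots * self.ppi) != 0:
            raise ValueError("n_pe must be divisible by n_shots * ppi")

    @property
    def etl(self) -> int:
        """Echo train length: phase-encode lines acquired per excitation."""
        return self.matrix[1] // (self.n_shots * self.ppi)

    @property
    def tr_vol_s(self) -> float:
        return self.tr_shot_ms * self.n_shots / 1000.0

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        return tuple(f / m for f, m in zip(self.fov_mm, self.matrix))


def ms_protocol(**overrides) -> SequenceParams:
    """The segmented (multishot) EPI protocol: TR 500 ms x 4 shots, 900 volumes."""
    p = dict(tr_shot_ms=500.0, n_shots=4, te_ms=17.0, flip_deg=60.0,
             matrix=(96, 96, 16), fov_mm=(35.0, 35.0, 16.0), bw_hz=250e3,
             ppi=2, n_rep=900)
    p.update(overrides)
    return SequenceParams(**p)


def ss_protocol(**overrides) -> SequenceParams:
    """The single-shot EPI protocol: TR 1000 ms, 1800 volumes."""
    p = dict(tr_shot_ms=1000.0, n_shots=1, te_ms=17.0, flip_deg=60.0,
             matrix=(96, 96, 16), fov_mm=(35.0, 35.0, 16.0), bw_hz=250e3,
             ppi=2, n_rep=1800)
    p.update(overrides)
    return SequenceParams(**p)


@dataclass
class NetworkSpec:
    """Planted resting-state networks: (name, member parcel ids, amplitude).

    Amplitude is the fractional BOLD fluctuation relative to baseline
    (0.02 = 2%).  band_hz is the pass band of the fluctuations;
    cross_network_correlation the shared-variance correlation between
    different networks' time courses.
    """

    networks: list[tuple[str, tuple[int, ...], float]]
    band_hz: tuple[float, float] = (0.01, 0.1)
    cross_network_correlation: float = 0.0

    def __post_init__(self) -> None:
        for name, members, amp in self.networks:
            if amp < 0:
                raise ValueError(f"network {name!r} has negative amplitude")
        if not (0 <= self.cross_network_correlation < 1):
            raise ValueError("cross_network_correlation must be in [0, 1)")

    def validate_against(self, phantom: Phantom) -> None:
        known = set(phantom.parcels["id"])
        for name, members, _ in self.networks:
            missing = set(members) - known
            if missing:
                raise ValueError(f"network {name!r}: unknown parcels {missing}")


@dataclass
class Volume4D:
    """An acquired or preprocessed 4D fMRI series (x, y, z, t)."""

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    tr_vol_s: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("Volume4D.data must be 4-dimensional")
        if self.tr_vol_s <= 0:
            raise ValueError("tr_vol_s must be positive")

    @property
    def n_t(self) -> int:
        return self.data.shape[-1]

    def copy_with(self, data: np.ndarray, **meta) -> "Volume4D":
        m = dict(self.meta)
        m.update(meta)
        return Volume4D(data, self.voxel_size, self.tr_vol_s, m)


# --------------------------------------------------------------------------- #
# phantom and field map construction
# --------------------------------------------------------------------------- #

def make_phantom(shape: tuple[int, int, int], n_cortical: int, n_subcortical: int,
                 seed: int, fov_mm: tuple[float, float, float] = (35.0, 35.0, 16.0),
                 pe_axis: int = 1, min_parcel_voxels: int = 2) -> Phantom:
    """Build an ellipsoidal brain phantom with parcellated tissue and air cavities.

    Cortical parcels tile the dorsal shell, subcortical parcels the remaining
    (ventral/deep) brain, each split into left/right hemisphere copies
    (anterior-posterior strips).  Two air cavities sit ventro-laterally,
    mimicking the aural cavities that drive susceptibility artifacts.

    Raises ValueError if the requested parcel count cannot be placed at this
    matrix size.
    """
    shape = tuple(int(s) for s in shape)
    if min(shape) < 4:
        raise ValueError("phantom shape too small (each axis must be >= 4)")
    if n_cortical < 1 or n_subcortical < 1:
        raise ValueError("need at least one cortical and one subcortical parcel")
    rng = np.random.default_rng(seed)
    voxel_size = tuple(f / s for f, s in zip(fov_mm, shape))

    ix, iy, iz = np.indices(shape).astype(float)
    c = [(s - 1) / 2.0 for s in shape]
    semi = [0.44 * s for s in shape]
    rho = np.sqrt(((ix - c[0]) / semi[0]) ** 2 + ((iy - c[1]) / semi[1]) ** 2
                  + ((iz - c[2]) / semi[2]) ** 2)
    brain = rho <= 1.0

    # cortical sheet: strictly dorsal shell; the ventro-lateral shell band
    # (where amygdala/insula-type structures sit, near the aural cavities)
    # belongs to the subcortical class
    dorsal = iz >= c[2] + 0.2 * semi[2]
    shell = (rho > 0.62) & brain
    cortical_region = shell & dorsal
    subcortical_region = brain & ~cortical_region

    labels = np.zeros(shape, dtype=np.int32)
    rows = []
    next_id = 1

    def _partition(region: np.ndarray, n_parc: int, prefix: str, klass: str) -> None:
        nonlocal next_id
        for hemi, hmask in (("L", ix < c[0]), ("R", ix >= c[0])):
            sel = region & hmask
            ys = iy[sel]
            if ys.size < n_parc * min_parcel_voxels:
                raise ValueError(
                    f"phantom too small: cannot fit {n_parc} {klass} parcels "
                    f"per hemisphere at shape {shape}")
            # anterior->posterior strips with balanced voxel counts
            qs = np.quantile(ys, np.linspace(0, 1, n_parc + 1))
            qs[-1] += 1.0
            for k in range(n_parc):
                pm = sel & (iy >= qs[k]) & (iy < qs[k + 1])
                if pm.sum() < min_parcel_voxels:
                    raise ValueError(
                        f"phantom too small: empty {klass} parcel at shape {shape}")
                labels[pm] = next_id
                rows.append(dict(id=next_id, name=f"{prefix}-{k + 1:02d}-{hemi}",
                                 hemisphere=hemi, klass=klass))
                next_id += 1

    def _partition_compact(region: np.ndarray, n_parc: int, prefix: str,
                           klass: str) -> None:
        """Compact parcels: farthest-point seeding + Lloyd iterations on the
        left hemisphere, centroids mirrored to the right so parcels come in
        anatomical L/R pairs."""
        nonlocal next_id
        left = region & (ix < c[0])
        pts = np.argwhere(left).astype(float)
        if pts.shape[0] < n_parc * min_parcel_voxels:
            raise ValueError(
                f"phantom too small: cannot fit {n_parc} {klass} parcels "
                f"per hemisphere at shape {shape}")
        cents = [pts[int(rng.integers(pts.shape[0]))]]
        for _ in range(n_parc - 1):
            d2 = np.min([((pts - cc) ** 2).sum(1) for cc in cents], axis=0)
            cents.append(pts[int(np.argmax(d2))])
        cents = np.array(cents)
        for _ in range(10):
            assign = np.argmin([((pts - cc) ** 2).sum(1) for cc in cents],
                               axis=0)
            for kk in range(n_parc):
                sel = pts[assign == kk]
                if len(sel):
                    cents[kk] = sel.mean(axis=0)
        # order parcels anterior -> posterior for stable naming
        cents = cents[np.argsort(cents[:, 1])]
        for hemi, hmask in (("L", ix < c[0]), ("R", ix >= c[0])):
            hc = cents.copy()
            if hemi == "R":
                hc[:, 0] = 2 * c[0] - hc[:, 0]       # mirror in x
            vox = np.argwhere(region & hmask).astype(float)
            assign = np.argmin([((vox - cc) ** 2).sum(1) for cc in hc], axis=0)
            for kk in range(n_parc):
                sel = vox[assign == kk].astype(int)
                if sel.shape[0] < min_parcel_voxels:
                    raise ValueError(
                        f"phantom too small: empty {klass} parcel at {shape}")
                labels[tuple(sel.T)] = next_id
                rows.append(dict(id=next_id, name=f"{prefix}-{kk + 1:02d}-{hemi}",
                                 hemisphere=hemi, klass=klass))
                next_id += 1

    _partition(cortical_region, n_cortical, "ctx", "cortical")
    _partition_compact(subcortical_region, n_subcortical, "sub", "subcortical")

    # air cavities: aural pair (ventro-lateral, posterior) and nasal pair
    # (ventro-medial, anterior) — the susceptibility sources of the rat head
    r_cav = max(2.0, 0.06 * shape[0])
    cavity_sites = [("ear", 0.78, -0.25, -0.70), ("nose", 0.35, -0.80, -0.70)]
    for site, fx, fy, fz in cavity_sites:
        for hemi, sx in (("L", -1.0), ("R", 1.0)):
            cav_c = np.array([c[0] + sx * fx * semi[0] + rng.uniform(-0.5, 0.5),
                              c[1] + fy * semi[1] + rng.uniform(-0.5, 0.5),
                              max(1.0, c[2] + fz * semi[2])])
            d2 = ((ix - cav_c[0]) ** 2 + (iy - cav_c[1]) ** 2
                  + (iz - cav_c[2]) ** 2)
            cav = d2 <= r_cav**2
            if cav.sum() < min_parcel_voxels:
                raise ValueError("phantom too small to place air cavities")
            labels[cav] = next_id
            rows.append(dict(id=next_id, name=f"cavity-{site}-{hemi}",
                             hemisphere=hemi, klass="air"))
            next_id += 1

    table = pd.DataFrame(rows)
    # every tissue parcel must have survived cavity carving
    for row in table.itertuples():
        n_vox = int((labels == row.id).sum())
        if n_vox < min_parcel_voxels:
            raise ValueError(f"parcel {row.name} lost to cavity carving")

    # smooth baseline: ~100 a.u. with a gentle seeded first-order gradient
    g = rng.uniform(-1, 1, size=3)
    trend = (g[0] * (ix - c[0]) / semi[0] + g[1] * (iy - c[1]) / semi[1]
             + g[2] * (iz - c[2]) / semi[2])
    baseline = 100.0 * (1.0 + 0.03 * trend)
    tissue = np.isin(labels, table.loc[table.klass != "air", "id"].to_numpy())
    baseline = np.where(tissue, baseline, 0.0)

    return Phantom(labels=labels, baseline=baseline, voxel_size=voxel_size,
                   pe_axis=pe_axis, parcels=table)


def make_fieldmap(phantom: Phantom, peak_hz: float, width_mm: float, seed: int,
                  background_hz: float = 0.0,
                  ventral_gradient_hz: float = 0.0) -> FieldMap:
    """Off-resonance field: Gaussian bumps at air-cavity centroids.

    Bump signs alternate (+, -, ...) so both stretching and compression occur,
    as around real aural cavities.  Optional smooth backgrounds: a seeded
    first-order term (``background_hz``) and a ventral shim-failure term
    (``ventral_gradient_hz``) — the field dips cubically toward the skull
    base, so its gradient grows with depth and vanishes at the dorsal
    surface, the way a shim optimized over dorsal cortex fails near the
    air-filled skull base.
    """
    if peak_hz < 0:
        raise ValueError("peak_hz must be >= 0")
    air_ids = phantom.parcel_ids("air")
    if len(air_ids) == 0:
        raise ValueError("phantom has no air-cavity parcels")
    shape = phantom.shape
    vs = np.asarray(phantom.voxel_size)
    coords = np.stack(np.indices(shape).astype(float), axis=-1) * vs

    delta = np.zeros(shape, dtype=float)
    sign = 1.0
    for pid in air_ids:
        cen = phantom.parcel_centroid(int(pid)) * vs
        d2 = ((coords - cen) ** 2).sum(axis=-1)
        delta += sign * peak_hz * np.exp(-d2 / (2.0 * width_mm**2))
        sign = -sign

    if background_hz > 0:
        rng = np.random.default_rng(seed)
        g = rng.uniform(-1, 1, size=3)
        c = [(s - 1) / 2.0 for s in shape]
        ix, iy, iz = np.indices(shape).astype(float)
        bg = (g[0] * (ix - c[0]) / shape[0] + g[1] * (iy - c[1]) / shape[1]
              + g[2] * (iz - c[2]) / shape[2])
        delta += background_hz * bg

    if ventral_gradient_hz > 0:
        idx = np.indices(shape).astype(float)
        iz = idx[2]
        z_top = shape[2] - 1.0
        depth = (z_top - iz) / z_top          # 0 dorsal .. 1 ventral
        pe = phantom.pe_axis
        pe_coord = (idx[pe] - (shape[pe] - 1) / 2.0) / shape[pe]
        delta -= ventral_gradient_hz * depth**4 * pe_coord

    return FieldMap(delta_f=delta, voxel_size=phantom.voxel_size)


# --------------------------------------------------------------------------- #
# EPI readout physics
# --------------------------------------------------------------------------- #

def pe_bandwidth_per_pixel(seq: SequenceParams) -> float:
    """Per-pixel bandwidth along the phase-encode axis, in Hz.

    bw_pe = 1 / (ETL * echo_spacing): segmentation shortens the echo train,
    raising the PE bandwidth and shrinking off-resonance displacement.
    """
    return 1.0 / (seq.etl * seq.echo_spacing_ms / 1000.0)


def pe_displacement(fmap: FieldMap, seq: SequenceParams,
                    pe_axis: int = 1) -> DisplacementField:
    """Signed voxel shift along the PE axis: Δf / per-pixel PE bandwidth."""
    bw = pe_bandwidth_per_pixel(seq)
    return DisplacementField(shift_vox=fmap.delta_f / bw, pe_axis=pe_axis)


def dropout_map(fmap: FieldMap, seq: SequenceParams, kappa: float) -> np.ndarray:
    """Susceptibility signal-loss map in (0, 1].

    attenuation = exp(-TE * ΔR2*), ΔR2* = kappa * |∇Δf| (central differences,
    Hz/mm).  A mesoscopic stand-in for intravoxel dephasing: attenuation is 1
    wherever the field is locally uniform.
    """
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    grads = np.gradient(fmap.delta_f, *fmap.voxel_size)
    gmag = np.sqrt(sum(g**2 for g in grads))
    te_s = seq.te_ms / 1000.0
    return np.exp(-te_s * kappa * gmag)


def ernst_signal(flip_deg: float, tr_shot_ms: float, t1_ms: float) -> float:
    """Relative steady-state gradient-echo signal at a given flip angle.

    S = sin(a) (1 - E1) / (1 - E1 cos(a)),  E1 = exp(-TR_shot / T1).
    Maximal at the Ernst angle acos(E1).
    """
    if not (0 <= flip_deg <= 180):
        raise ValueError("flip angle must be in [0, 180] degrees")
    if tr_shot_ms <= 0 or t1_ms <= 0:
        raise ValueError("times must be positive")
    a = math.radians(flip_deg)
    e1 = math.exp(-tr_shot_ms / t1_ms)
    return math.sin(a) * (1.0 - e1) / (1.0 - e1 * math.cos(a))


# --------------------------------------------------------------------------- #
# BOLD time courses and acquisition
# --------------------------------------------------------------------------- #

def _fft_band_limit(x: np.ndarray, dt_s: float, band: tuple[float, float]) -> np.ndarray:
    """Hard band-limit rows of x (shape (k, n_t)) to band (Hz)."""
    n_t = x.shape[-1]
    f = np.fft.rfftfreq(n_t, d=dt_s)
    mask = (f >= band[0]) & (f <= band[1])
    xf = np.fft.rfft(x, axis=-1)
    xf[..., ~mask] = 0.0
    return np.fft.irfft(xf, n=n_t, axis=-1)


def simulate_network_timecourses(spec: NetworkSpec, n_t: int, tr_vol_s: float,
                                 seed: int) -> np.ndarray:
    """Zero-mean unit-variance band-limited network time courses (K, n_t).

    Cross-network correlation c is induced by mixing each network's private
    series with a shared series: x_k = sqrt(1-c) e_k + sqrt(c) g.
    """
    if n_t < 16:
        raise ValueError("n_t must be >= 16")
    nyq = 1.0 / (2.0 * tr_vol_s)
    lo, hi = spec.band_hz
    if not (0 < lo < hi < nyq):
        raise ValueError(f"band {spec.band_hz} outside (0, Nyquist={nyq:g})")
    k = len(spec.networks)
    c = spec.cross_network_correlation
    if k > 1 and (k - 1) * c >= 1.0:
        raise ValueError("cross_network_correlation too large for this many "
                         "networks ((k-1)*c must be < 1)")
    n_pairs = k * (k - 1) // 2
    n_src = k + n_pairs
    if n_src >= n_t // 2:
        raise ValueError("too many networks for this series length")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal((n_src, n_t))
    filt = _fft_band_limit(white, tr_vol_s, (lo, hi))
    filt -= filt.mean(axis=-1, keepdims=True)
    # orthonormalize in-sample so every pairwise correlation is exact: each
    # network mixes its private series with one independent shared channel
    # per partner network, rather than one global common mode
    q, _ = np.linalg.qr(filt.T)
    base = q.T * math.sqrt(n_t)                  # unit-variance, orthogonal
    private = base[:k]
    shared = base[k:]
    mixed = np.sqrt(max(0.0, 1.0 - (k - 1) * c)) * private
    if c > 0 and k > 1:
        pair_idx = 0
        for a in range(k):
            for b in range(a + 1, k):
                mixed[a] = mixed[a] + math.sqrt(c) * shared[pair_idx]
                mixed[b] = mixed[b] + math.sqrt(c) * shared[pair_idx]
                pair_idx += 1
    mixed -= mixed.mean(axis=-1, keepdims=True)
    mixed /= mixed.std(axis=-1, keepdims=True)
    return mixed


def _pe_warp_indices(shift_vox: np.ndarray, pe_axis: int):
    """Precompute gather indices/weights for a pull-based PE-axis warp.

    out[i] = in[i - shift[i]] with linear interpolation; samples outside the
    grid read as 0 (air).
    """
    n = shift_vox.shape[pe_axis]
    idx = np.arange(n).reshape([-1 if a == pe_axis else 1
                                for a in range(shift_vox.ndim)])
    pos = idx - shift_vox
    flo = np.floor(pos).astype(np.int64)
    w = pos - flo
    v0 = (flo >= 0) & (flo <= n - 1)
    v1 = (flo + 1 >= 0) & (flo + 1 <= n - 1)
    i0 = np.clip(flo, 0, n - 1)
    i1 = np.clip(flo + 1, 0, n - 1)
    return i0, i1, w, v0, v1


def warp_pe(data: np.ndarray, shift_vox: np.ndarray, pe_axis: int) -> np.ndarray:
    """Warp a 3D volume along pe_axis by a signed voxel shift map.

    Exact pass-through when shift is identically zero.
    """
    if not np.any(shift_vox):
        return data.copy()
    i0, i1, w, v0, v1 = _pe_warp_indices(shift_vox, pe_axis)
    a = np.take_along_axis(data, i0, axis=pe_axis)
    b = np.take_along_axis(data, i1, axis=pe_axis)
    return (1.0 - w) * a * v0 + w * b * v1


def acquisition_time_min(seq: SequenceParams) -> float:
    """Total acquisition time in minutes: tr_shot * n_shots * n_rep."""
    return seq.tr_shot_ms * seq.n_shots * seq.n_rep / 60000.0


def acquire_series(phantom: Phantom, fmap: FieldMap, seq: SequenceParams,
                   spec: NetworkSpec, motion_spike_times: tuple[int, ...] = (),
                   seed: int = 0, kappa: float = 1.5,
                   kappa_readout: float = 3.0,
                   spike_jump_frac: float = 0.02,
                   tc_seed: int | None = None,
                   tcs: np.ndarray | None = None,
                   regional_tcs: np.ndarray | None = None) -> Volume4D:
    """Simulate a full 4D EPI acquisition.

    Per volume: signal = baseline * Ernst * dropout * readout-dephasing *
    T2'-decay * (1 + sum_k amplitude_k * membership_k * s_k(t)) plus
    parcel-coherent structured noise (sigma_regional); warped along the PE
    axis by the off-resonance displacement; scaled by (1 + eta_t) inter-shot
    instability; motion-spike volumes get a 1-voxel PE translation plus a
    global intensity jump; thermal Gaussian noise is added last.

    The readout-dephasing factor exp(-kappa_readout * T_etl * |d(Δf)/d(pe)|)
    (T_etl = ETL * echo spacing, gradient in Hz/voxel) is where segmentation
    pays off: phase errors accumulate over the echo train and are reset on
    each RF pulse, so the attenuation near susceptibility gradients is
    4x milder for a 4-shot acquisition.

    sigma_regional adds an independent band-limited fluctuation per tissue
    parcel, uniform over the parcel and of fixed amplitude in image units —
    the structured (physiological/instrumental) noise floor that parcel
    averaging cannot remove.

    field_instability models respiration-driven temporal fluctuation of the
    off-resonance field: the displacement map is scaled by (1 + eps_t),
    eps_t ~ N(0, field_instability), each volume.  Because displacement is
    Δf over the per-pixel PE bandwidth, the same physiological fluctuation
    moves a single-shot image 4x more than a 4-shot image — the temporal
    face of the distortion penalty.
    """
    spec.validate_against(phantom)
    for t_spike in motion_spike_times:
        if not (0 <= t_spike < seq.n_rep):
            raise IndexError(f"spike time {t_spike} outside [0, {seq.n_rep})")
    if fmap.delta_f.shape != phantom.shape:
        raise ValueError("field map / phantom shape mismatch")

    ernst = ernst_signal(seq.flip_deg, seq.tr_shot_ms, seq.t1_ms)
    att = dropout_map(fmap, seq, kappa)
    t2s_factor = math.exp(-seq.te_ms / seq.t2s_ms)
    # echo-train dephasing: accumulates over the readout, reset per shot
    t_etl_s = seq.etl * seq.echo_spacing_ms / 1000.0
    g_pe = np.abs(np.gradient(fmap.delta_f, axis=phantom.pe_axis))  # Hz/voxel
    att_ro = np.exp(-kappa_readout * t_etl_s * g_pe)
    static = phantom.baseline * ernst * att * att_ro * t2s_factor

    # tc_seed/tcs may be supplied so the same "digital animal" (identical
    # network fluctuations) can be scanned by both sequences
    if tc_seed is None:
        tc_seed = derive_seed(seed, 1)
    noise_seed = derive_seed(seed, 2)
    if tcs is None:
        tcs = simulate_network_timecourses(spec, seq.n_rep, seq.tr_vol_s,
                                           tc_seed)
    elif tcs.shape != (len(spec.networks), seq.n_rep):
        raise ValueError("supplied tcs must have shape (n_networks, n_rep)")

    regional = None
    if seq.sigma_regional > 0:
        tissue_ids = [int(i) for i in
                      phantom.parcels.loc[phantom.parcels.klass != "air", "id"]]
        if regional_tcs is not None:
            if regional_tcs.shape != (len(tissue_ids), seq.n_rep):
                raise ValueError("regional_tcs must be (n_tissue_parcels, "
                                 "n_rep)")
            reg = regional_tcs.copy()
        else:
            reg_rng_seed = derive_seed(seed, 3)
            white = np.random.default_rng(reg_rng_seed).standard_normal(
                (len(tissue_ids), seq.n_rep))
            reg = _fft_band_limit(white, seq.tr_vol_s, spec.band_hz)
        reg -= reg.mean(axis=-1, keepdims=True)
        reg /= reg.std(axis=-1, keepdims=True)
        pidx = np.full(phantom.shape, -1, dtype=np.int32)
        for pi, pid in enumerate(tissue_ids):
            pidx[phantom.labels == pid] = pi
        regional = (pidx, pidx >= 0, seq.sigma_regional * reg)

    shift = pe_displacement(fmap, seq, phantom.pe_axis).shift_vox
    warp = bool(np.any(shift))
    jitter = warp and seq.field_instability > 0
    if warp and not jitter:
        i0, i1, w, v0, v1 = _pe_warp_indices(shift, phantom.pe_axis)
    if jitter:
        # aliased respiratory field fluctuation: slow, in the BOLD band
        w = np.random.default_rng(derive_seed(seed, 4)).standard_normal(
            (1, seq.n_rep))
        eps = _fft_band_limit(w, seq.tr_vol_s, spec.band_hz)[0]
        eps *= seq.field_instability / eps.std()

    rng = np.random.default_rng(noise_seed)
    eta = (rng.normal(0.0, seq.shot_instability, size=seq.n_rep)
           if seq.shot_instability > 0 else np.zeros(seq.n_rep))
    brain = static > 0
    jump = spike_jump_frac * (static[brain].mean() if brain.any() else 0.0)
    spikes = set(int(t) for t in motion_spike_times)

    memberships = [(np.isin(phantom.labels, list(members)), amp)
                   for _, members, amp in spec.networks]

    out = np.empty(phantom.shape + (seq.n_rep,), dtype=np.float32)
    for t in range(seq.n_rep):
        mod = np.ones(phantom.shape)
        for k, (m, amp) in enumerate(memberships):
            if amp > 0:
                mod += amp * tcs[k, t] * m
        vol = static * mod
        if regional is not None:
            pidx, in_parcel, reg = regional
            vol = vol + np.where(in_parcel, reg[pidx.clip(min=0), t], 0.0)
        if jitter:
            i0, i1, w, v0, v1 = _pe_warp_indices(shift * (1.0 + eps[t]),
                                                 phantom.pe_axis)
        if warp:
            a = np.take_along_axis(vol, i0, axis=phantom.pe_axis)
            b = np.take_along_axis(vol, i1, axis=phantom.pe_axis)
            vol = (1.0 - w) * a * v0 + w * b * v1
        vol = vol * (1.0 + eta[t])
        if t in spikes:
            vol = np.roll(vol, 1, axis=phantom.pe_axis) + jump
        out[..., t] = vol
    if seq.sigma_thermal > 0:
        out += rng.normal(0.0, seq.sigma_thermal, size=out.shape).astype(np.float32)

    meta = dict(seed=int(seed), tc_seed=int(tc_seed), kappa=float(kappa),
                spike_times=sorted(spikes), n_shots=seq.n_shots,
                tr_shot_ms=seq.tr_shot_ms)
    return Volume4D(data=out, voxel_size=phantom.voxel_size,
                    tr_vol_s=seq.tr_vol_s, meta=meta)


def make_confounds(n_rep: int, spike_times: tuple[int, ...] = (), seed: int = 0,
                   motion_sd: float = 0.01, dt_s: float = 2.0,
                   tau_s: float = 20.0) -> pd.DataFrame:
    """Synthetic 12-column motion confound table (3 trans, 3 rot, derivatives).

    Motion is a continuous-time Ornstein-Uhlenbeck drift with correlation
    time ``tau_s``, sampled at the volume rate (phi = exp(-dt/tau)), so its
    spectral content is independent of the sequence's TR; spike volumes add a
    1-voxel jump to the phase-encode translation trace, mirroring what the
    acquisition model does to the images.
    """
    rng = np.random.default_rng(seed)
    names = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
    phi = math.exp(-dt_s / tau_s)
    base = np.zeros((n_rep, 6))
    for j in range(6):
        e = rng.normal(0, motion_sd, n_rep)
        for t in range(1, n_rep):
            base[t, j] = phi * base[t - 1, j] + e[t]
    for t_spike in spike_times:
        base[int(t_spike), 1] += 1.0
    deriv = np.vstack([np.zeros((1, 6)), np.diff(base, axis=0)])
    table = pd.DataFrame(np.hstack([base, deriv]),
                         columns=names + [f"d_{n}" for n in names])
    return table
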