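"""Shared inference engine: t statistics, Fisher z, TFCE, permutation FWE,
and noncentral-t power analysis.

TFCE (threshold-free cluster enhancement) integrates cluster extent^E *
height^H over all thresholds, boosting spatially coherent signal without a
fixed cluster-forming threshold.  Family-wise error is controlled by the
permutation distribution of the image-wide maximum TFCE statistic; sign-flip
permutations for one-sample designs, group-label shuffles for two-sample.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, special
from scipy import stats as sps

__all__ = [
    "StatMap", "PowerSpec", "one_sample_t", "t_to_z", "fisher_z", "tfce",
    "permutation_fwe", "required_sample_size",
]

Z_CLAMP = 8.0


@dataclass
class StatMap:
    """Voxelwise statistic with its TFCE enhancement and FWE-corrected 1-p."""

    stat: np.ndarray
    tfce: np.ndarray
    one_minus_p: np.ndarray
    meta: dict = field(default_factory=dict)


@dataclass
class PowerSpec:
    """Inputs of a one-sample t power / sample-size request."""

    alpha: float = 0.05
    power: float = 0.8
    effect_size: float = 1.0       # d = mean / SD (possibly offset upstream)
    z0: float | None = None        # optional offset threshold, applied upstream

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1) or not (0 < self.power < 1):
            raise ValueError("alpha and power must lie in (0, 1)")


def one_sample_t(x: np.ndarray, axis: int = 0):
    """One-sample t over ``axis``: t = mean / (sd / sqrt(n)), sample SD.

    Returns (t, z) where z is the standard-normal equivalent of t (clamped at
    |z| = 8).  Zero-SD entries take the clamped value with the sign of the
    mean (0 for an all-zero sample).
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[axis]
    if n < 2:
        raise ValueError("need at least two samples")
    m = x.mean(axis=axis)
    sd = x.std(axis=axis, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, m / (sd / math.sqrt(n)),
                     np.sign(m) * np.inf)
    z = t_to_z(t, n - 1)
    t = np.where(np.isfinite(t), t, np.sign(m) * Z_CLAMP * 1e6)
    return t, z


def t_to_z(t: np.ndarray, df: int) -> np.ndarray:
    """Map t to its standard-normal quantile equivalent, clamped at +/-8."""
    t = np.asarray(t, dtype=float)
    with np.errstate(all="ignore"):
        z = np.where(t < 0,
                     special.ndtri(sps.t.cdf(t, df)),
                     -special.ndtri(sps.t.sf(t, df)))
    z = np.nan_to_num(z, nan=0.0, posinf=Z_CLAMP, neginf=-Z_CLAMP)
    return np.clip(z, -Z_CLAMP, Z_CLAMP)


def fisher_z(r, clip: float = 1.0 - 1e-7):
    """Variance-stabilizing Fisher transform z = atanh(r), |r| clipped."""
    r = np.clip(np.asarray(r, dtype=float), -clip, clip)
    return np.arctanh(r)


def _structure(ndim: int, connectivity: int) -> np.ndarray:
    if connectivity in (26, 8):          # full neighbourhood
        return np.ones((3,) * ndim, dtype=bool)
    if connectivity in (6, 4):           # faces only
        return ndimage.generate_binary_structure(ndim, 1)
    if connectivity == 18:
        return ndimage.generate_binary_structure(ndim, 2)
    raise ValueError(f"unsupported connectivity {connectivity}")


def tfce(stat_map: np.ndarray, E: float = 0.5, H: float = 2.0,
         dh: float | None = None, connectivity: int = 26) -> np.ndarray:
    """Threshold-free cluster enhancement of the positive part of a map.

    TFCE(v) = sum over thresholds h = dh, 2dh, ... <= max of
    extent(v, h)^E * h^H * dh, where extent is the size of the connected
    component containing v at threshold h.  Callers enhance the negative
    direction by passing the negated map.
    """
    x = np.asarray(stat_map, dtype=float)
    pos = np.clip(x, 0.0, None)
    hmax = pos.max() if pos.size else 0.0
    out = np.zeros_like(pos)
    if hmax <= 0:
        return out
    if dh is None:
        dh = hmax / 100.0
    if dh <= 0:
        raise ValueError("dh must be positive")
    struct = _structure(x.ndim, connectivity)
    h = dh
    while h <= hmax * (1 + 1e-12):
        mask = pos >= h
        lab, _ = ndimage.label(mask, structure=struct)
        sizes = np.bincount(lab.ravel())
        out[mask] += sizes[lab[mask]] ** E * h**H * dh
        h += dh
    return out


def _two_sample_t(data: np.ndarray, is_a: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t (a - b) over axis 0."""
    a, b = data[is_a], data[~is_a]
    na, nb = a.shape[0], b.shape[0]
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (ma - mb) / denom, 0.0)
    return t


def permutation_fwe(data: np.ndarray, design: str = "one_sample",
                    labels: np.ndarray | None = None, n_perm: int = 999,
                    seed: int = 0, mask: np.ndarray | None = None,
                    E: float = 0.5, H: float = 2.0, dh: float | None = None,
                    connectivity: int = 26):
    """Max-statistic permutation FWE test with TFCE, both directions.

    data: (n_subjects, *volume).  One-sample designs sign-flip subjects;
    two-sample designs shuffle the binary group labels (True = group a,
    statistic direction a > b).  When the full permutation group is no larger
    than n_perm it is enumerated exhaustively; otherwise n_perm random
    permutations are drawn and the identity is always included, giving
    p(v) = (1 + #{perm: max TFCE >= TFCE_obs(v)}) / (n_perm + 1).

    Returns (StatMap_pos, StatMap_neg) for the two one-sided directions.
    """
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    vol_shape = data.shape[1:]
    if mask is None:
        mask = np.ones(vol_shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)

    if design == "one_sample":
        if n < 2:
            raise ValueError("one-sample design needs >= 2 subjects")
        total = 2**n if n < 63 else np.inf
    elif design == "two_sample":
        if labels is None:
            raise ValueError("two-sample design requires labels")
        is_a = np.asarray(labels, dtype=bool)
        na = int(is_a.sum())
        if na < 2 or n - na < 2:
            raise ValueError("two-sample design needs >= 2 subjects per group")
        total = math.comb(n, na)
    else:
        raise ValueError(f"unknown design {design!r}")

    def _masked_tfce(t_map):
        tm = np.where(mask, t_map, 0.0)
        return (tfce(tm, E, H, dh, connectivity),
                tfce(-tm, E, H, dh, connectivity))

    def _stat_for(perm):
        if design == "one_sample":
            signs = perm.reshape((-1,) + (1,) * len(vol_shape))
            x = data * signs
            m = x.mean(axis=0)
            sd = x.std(axis=0, ddof=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                return np.where(sd > 0, m * math.sqrt(n) / sd, 0.0)
        return _two_sample_t(data, perm)

    if design == "one_sample":
        identity = np.ones(n)
    else:
        identity = is_a

    t_obs = _stat_for(identity)
    tfce_pos, tfce_neg = _masked_tfce(t_obs)

    rng = np.random.default_rng(seed)
    exhaustive = np.isfinite(total) and total <= n_perm
    if exhaustive:
        if design == "one_sample":
            perms = [np.array(s, dtype=float)
                     for s in itertools.product((1.0, -1.0), repeat=n)]
        else:
            perms = []
            for comb in itertools.combinations(range(n), na):
                lab = np.zeros(n, dtype=bool)
                lab[list(comb)] = True
                perms.append(lab)
    else:
        perms = []
        for _ in range(n_perm):
            if design == "one_sample":
                perms.append(rng.choice([1.0, -1.0], size=n))
            else:
                lab = np.zeros(n, dtype=bool)
                lab[rng.permutation(n)[:na]] = True
                perms.append(lab)

    max_pos = np.empty(len(perms))
    max_neg = np.empty(len(perms))
    for i, perm in enumerate(perms):
        tp, tn = _masked_tfce(_stat_for(perm))
        max_pos[i] = tp.max()
        max_neg[i] = tn.max()

    if exhaustive:
        p_pos = _p_from_null(tfce_pos, max_pos, denom=len(perms), plus_one=0)
        p_neg = _p_from_null(tfce_neg, max_neg, denom=len(perms), plus_one=0)
        n_eff = len(perms)
    else:
        p_pos = _p_from_null(tfce_pos, max_pos, denom=len(perms) + 1, plus_one=1)
        p_neg = _p_from_null(tfce_neg, max_neg, denom=len(perms) + 1, plus_one=1)
        n_eff = len(perms) + 1

    meta = dict(design=design, n_perm=n_eff, exhaustive=bool(exhaustive),
                seed=int(seed), E=E, H=H, dh=dh, connectivity=connectivity)
    pos = StatMap(stat=t_obs, tfce=tfce_pos, one_minus_p=1.0 - p_pos, meta=meta)
    neg = StatMap(stat=-t_obs, tfce=tfce_neg, one_minus_p=1.0 - p_neg,
                  meta=dict(meta, direction="negated"))
    return pos, neg


def _p_from_null(obs: np.ndarray, null_max: np.ndarray, denom: int,
                 plus_one: int) -> np.ndarray:
    srt = np.sort(null_max)
    # count of null maxima >= obs(v)
    ge = len(srt) - np.searchsorted(srt, obs, side="left")
    return (plus_one + ge) / denom


def required_sample_size(effect_size: float | None = None, alpha: float = 0.05,
                         power: float = 0.8, spec: PowerSpec | None = None,
                         n_max: int = 100000) -> int:
    """Smallest n with power >= target for a two-sided one-sample t-test.

    Power is computed exactly from the noncentral t distribution with
    noncentrality d * sqrt(n) at level alpha, df = n - 1.
    """
    if spec is not None:
        effect_size, alpha, power = spec.effect_size, spec.alpha, spec.power
    if effect_size is None or effect_size <= 0:
        raise ValueError("effect size must be positive")
    d = float(effect_size)
    for n in range(2, n_max + 1):
        df = n - 1
        tc = sps.t.ppf(1.0 - alpha / 2.0, df)
        nc = d * math.sqrt(n)
        pw = sps.nct.sf(tc, df, nc) + sps.nct.cdf(-tc, df, nc)
        if pw >= power:
            return n
    raise ValueError("requested power unreachable within n_max")
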