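"""Spatial ICA, rule-based component classification, non-aggressive denoising,
dual regression, and group comparison of component maps.

The decomposition is spatial ICA on PCA-whitened data (fixed-point
negentropy maximisation with symmetric decorrelation and tanh contrast —
the FastICA algorithm).  Component classification replaces a trained
classifier with three transparent deterministic rules on frequency content,
out-of-brain map mass, and time-course spikes; the downstream contract
(remove planted noise, keep planted signal) is what the tests check.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from . import stats as _stats
from .synth import Volume4D, derive_seed

logger = logging.getLogger(__name__)

__all__ = ["ComponentSet", "subject_ica", "classify_components",
           "denoise_nonaggressive", "group_ica", "dual_regression",
           "compare_component_maps", "match_components"]

DEFAULT_RULES = dict(hf_cut_hz=0.1, hf_frac=0.5, edge_frac=0.33, kurtosis=10.0)


@dataclass
class ComponentSet:
    """ICA decomposition: spatial maps, time courses, labels, metadata.

    maps: (k, X, Y, Z), z-scored over mask voxels, positive-skew sign
    convention, ordered by explained variance.  timecourses: (k, t).
    """

    maps: np.ndarray
    timecourses: np.ndarray
    mask: np.ndarray
    explained_variance: np.ndarray
    labels: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    @property
    def n_components(self) -> int:
        return self.maps.shape[0]


def _run_ica(X: np.ndarray, n_components: int, seed: int, max_retries: int = 3,
             on_nonconvergence: str = "error"):
    """FastICA with retry-on-nonconvergence (derived seeds).

    X is (t, v): rows are (pseudo) time points, columns voxels.  Returns
    (S (v, k) spatial sources, A (t, k) mixing/time courses).

    Trailing components of noisy data are near-Gaussian, and the symmetric
    fixed-point rotation among them need not settle to a tight tolerance.
    ``on_nonconvergence='error'`` raises after the retries (the strict
    contract); ``'warn'`` accepts the final attempt with a logged warning,
    which is the appropriate policy when the decomposition is used for
    denoising rather than source identification.
    """
    last = None
    for attempt in range(max_retries):
        rs = seed if attempt == 0 else derive_seed(seed, 1000 + attempt)
        ica = FastICA(n_components=n_components, algorithm="parallel",
                      whiten="unit-variance", fun="logcosh", max_iter=500,
                      tol=1e-6, random_state=rs)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            S = ica.fit_transform(X.T)
        conv = [w for w in caught if issubclass(w.category, ConvergenceWarning)]
        if not conv:
            return S, ica.mixing_
        last = (S, ica.mixing_)
        logger.warning("ICA did not converge (attempt %d/%d)", attempt + 1,
                       max_retries)
    if on_nonconvergence == "warn":
        logger.warning("accepting non-converged ICA (rotation of trailing "
                       "near-Gaussian components undetermined)")
        return last
    raise RuntimeError(f"ICA failed to converge after {max_retries} attempts")


def _finalize(S: np.ndarray, A: np.ndarray, mask: np.ndarray,
              vol_shape: tuple, meta: dict) -> ComponentSet:
    """Order by explained variance, z-score maps, fix sign to positive skew."""
    k = S.shape[1]
    energy = (np.linalg.norm(A, axis=0) * np.linalg.norm(S, axis=0)) ** 2
    order = np.argsort(energy)[::-1]
    S, A, energy = S[:, order], A[:, order], energy[order]
    ev = energy / energy.sum() if energy.sum() > 0 else np.zeros(k)

    maps = np.zeros((k,) + vol_shape)
    tcs = np.empty((k, A.shape[0]))
    for i in range(k):
        s = S[:, i]
        sd = s.std()
        s = (s - s.mean()) / (sd if sd > 0 else 1.0)
        if sps.skew(s) < 0:
            s = -s
            A[:, i] = -A[:, i]
        maps[i][mask] = s
        tcs[i] = A[:, i]
    return ComponentSet(maps=maps, timecourses=tcs, mask=mask,
                        explained_variance=ev,
                        labels=["unlabeled"] * k, meta=meta)


def subject_ica(vol: Volume4D, mask: np.ndarray, n_components: int = 70,
                seed: int = 0, on_nonconvergence: str = "error") -> ComponentSet:
    """Subject-level spatial ICA with ``n_components`` components."""
    mask = np.asarray(mask, dtype=bool)
    if vol.n_t <= n_components:
        raise ValueError("need more time points than components")
    X = vol.data[mask].T.astype(float)          # (t, v)
    X = X - X.mean(axis=0, keepdims=True)
    S, A = _run_ica(X, n_components, seed, on_nonconvergence=on_nonconvergence)
    meta = dict(level="subject", seed=int(seed), algorithm="fastica-parallel",
                contrast="tanh", tol=1e-6, tr_vol_s=vol.tr_vol_s)
    return _finalize(S, A, mask, vol.data.shape[:3], meta)


def classify_components(cs: ComponentSet, brain_mask: np.ndarray,
                        tr_vol_s: float, rules: dict | None = None) -> list[str]:
    """Deterministic noise/signal labels.

    A component is noise iff any rule fires:
      (i)  > ``hf_frac`` of time-course spectral power above ``hf_cut_hz``;
      (ii) > ``edge_frac`` of |map| mass outside the brain mask;
      (iii) time-course excess kurtosis > ``kurtosis`` (spikes).
    """
    r = dict(DEFAULT_RULES)
    if rules:
        r.update(rules)
    brain = np.asarray(brain_mask, dtype=bool)
    labels = []
    f = np.fft.rfftfreq(cs.timecourses.shape[1], d=tr_vol_s)
    hf = f > r["hf_cut_hz"]
    for i in range(cs.n_components):
        tc = cs.timecourses[i] - cs.timecourses[i].mean()
        psd = np.abs(np.fft.rfft(tc)) ** 2
        tot = psd.sum()
        hf_frac = psd[hf].sum() / tot if tot > 0 else 0.0
        amap = np.abs(cs.maps[i])
        mass = amap[cs.mask].sum()
        outside = amap[cs.mask & ~brain].sum()
        edge_frac = outside / mass if mass > 0 else 0.0
        kurt = sps.kurtosis(cs.timecourses[i], fisher=True)
        noise = (hf_frac > r["hf_frac"] or edge_frac > r["edge_frac"]
                 or kurt > r["kurtosis"])
        labels.append("noise" if noise else "signal")
    cs.labels = labels
    return labels


def denoise_nonaggressive(vol: Volume4D, cs: ComponentSet) -> Volume4D:
    """Remove only the variance uniquely attributable to noise components.

    All component time courses are fit jointly by least squares per voxel;
    the partial fit of the noise-labelled columns is subtracted.  With no
    noise labels the data pass through unchanged.
    """
    noise_idx = [i for i, l in enumerate(cs.labels) if l == "noise"]
    if not noise_idx:
        return vol.copy_with(vol.data.copy(), denoised="no-noise-components")
    D = cs.timecourses.T.astype(float)           # (t, k)
    D = D - D.mean(axis=0, keepdims=True)
    X = np.hstack([np.ones((D.shape[0], 1)), D])
    Y = vol.data.reshape(-1, vol.n_t).T          # (t, v)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    fit_noise = X[:, [j + 1 for j in noise_idx]] @ beta[[j + 1 for j in noise_idx]]
    out = (Y - fit_noise).T.reshape(vol.data.shape)
    return vol.copy_with(out.astype(vol.data.dtype, copy=False),
                         denoised=f"nonaggressive:{len(noise_idx)}")


def group_ica(subjects: list[Volume4D], mask: np.ndarray, d: int = 30,
              seed: int = 0, arms: list[str] | None = None,
              subject_reduction: int | None = None,
              on_nonconvergence: str = "error") -> ComponentSet:
    """Group-level spatial ICA by temporal concatenation.

    Each subject is voxelwise variance-normalised, reduced to
    ``subject_reduction`` temporal principal components (default min(2d,
    t-1)), and the reduced series are stacked before a single ICA with ``d``
    components.  Pooling both acquisition arms in one call keeps the group
    estimate unbiased; single-arm input is allowed but logged as a warning.
    """
    if len(subjects) < 2:
        raise ValueError("group ICA needs at least 2 subjects")
    mask = np.asarray(mask, dtype=bool)
    shape = subjects[0].data.shape[:3]
    for s in subjects:
        if s.data.shape[:3] != shape:
            raise ValueError("subject volume shapes differ")
    if arms is not None and len(set(arms)) < 2:
        logger.warning("group ICA on a single acquisition arm: group "
                       "components will be biased toward that arm")
    blocks = []
    for i, s in enumerate(subjects):
        X = s.data[mask].T.astype(float)         # (t, v)
        X = X - X.mean(axis=0, keepdims=True)
        sd = X.std(axis=0, keepdims=True)
        X = X / np.where(sd > 0, sd, 1.0)
        r = subject_reduction or min(2 * d, X.shape[0] - 1)
        r = min(r, X.shape[0])
        U, sv, Vt = np.linalg.svd(X, full_matrices=False)
        blocks.append(sv[:r, None] * Vt[:r])     # PCA pseudo time points
    Xg = np.vstack(blocks)
    if Xg.shape[0] <= d:
        raise ValueError("too few concatenated components for the requested d")
    S, A = _run_ica(Xg, d, seed, on_nonconvergence=on_nonconvergence)
    meta = dict(level="group", seed=int(seed), n_subjects=len(subjects),
                arms=sorted(set(arms)) if arms else None,
                pooled_arms=bool(arms and len(set(arms)) >= 2),
                subject_reduction=int(blocks[0].shape[0]))
    return _finalize(S, A, mask, shape, meta)


def dual_regression(group_maps: ComponentSet, subject_vol: Volume4D):
    """Two-stage least squares mapping group components into a subject.

    Stage 1 regresses the (demeaned) group spatial maps against each time
    point, yielding subject time courses; stage 2 regresses those time
    courses (variance-normalised) against each voxel series, yielding
    subject-specific spatial maps.

    Returns (timecourses (k, t), maps (k, X, Y, Z)).
    """
    mask = group_maps.mask
    if subject_vol.data.shape[:3] != group_maps.maps.shape[1:]:
        raise ValueError("group maps and subject volume grids differ")
    M = group_maps.maps[:, mask].T.astype(float)     # (v, k)
    M = M - M.mean(axis=0, keepdims=True)
    k = M.shape[1]
    rank = np.linalg.matrix_rank(M)
    if rank < k:
        # name the components whose removal restores full rank
        bad = []
        keep = list(range(k))
        for i in range(k):
            others = [j for j in keep if j != i]
            if np.linalg.matrix_rank(M[:, others]) == rank:
                bad.append(i)
        raise ValueError(f"group maps are rank deficient (rank {rank} < {k}); "
                         f"collinear components: {bad}")
    X1 = np.hstack([np.ones((M.shape[0], 1)), M])
    Y = subject_vol.data[mask].astype(float)         # (v, t)
    beta1, *_ = np.linalg.lstsq(X1, Y, rcond=None)
    tcs = beta1[1:]                                  # (k, t)

    T = tcs.T - tcs.T.mean(axis=0, keepdims=True)    # (t, k)
    sd = T.std(axis=0, keepdims=True)
    T = T / np.where(sd > 0, sd, 1.0)
    X2 = np.hstack([np.ones((T.shape[0], 1)), T])
    Y2 = subject_vol.data.reshape(-1, subject_vol.n_t).T
    beta2, *_ = np.linalg.lstsq(X2, Y2, rcond=None)
    maps = beta2[1:].reshape((k,) + subject_vol.data.shape[:3])
    return tcs, maps


def match_components(maps_a: np.ndarray, maps_b: np.ndarray,
                     mask: np.ndarray) -> list[tuple[int, int, float]]:
    """Greedy max-|spatial correlation| matching between two component sets.

    Returns (index_a, index_b, |r|) triples, one per component of ``maps_a``.
    """
    mask = np.asarray(mask, dtype=bool)
    A = np.stack([m[mask] for m in maps_a])
    B = np.stack([m[mask] for m in maps_b])
    C = np.corrcoef(A, B)[: len(A), len(A):]
    C = np.abs(np.nan_to_num(C))
    pairs = []
    used = set()
    for _ in range(min(len(A), len(B))):
        i, j = np.unravel_index(np.argmax(C), C.shape)
        pairs.append((int(i), int(j), float(C[i, j])))
        used.add(j)
        C[i, :] = -1
        C[:, j] = -1
    return pairs


def compare_component_maps(maps_a: np.ndarray, maps_b: np.ndarray,
                           component_ids, n_perm: int = 500, seed: int = 0,
                           mask: np.ndarray | None = None, **tfce_kw) -> dict:
    """Two-sample permutation TFCE/FWE test per selected component.

    maps_a/maps_b: (n_subjects, k, X, Y, Z) stage-2 dual-regression maps per
    arm.  Returns {component_id: (StatMap a>b, StatMap b>a)}.
    """
    maps_a = np.asarray(maps_a)
    maps_b = np.asarray(maps_b)
    if maps_a.shape[0] < 3 or maps_b.shape[0] < 3:
        raise ValueError("need at least 3 subjects per arm")
    k = maps_a.shape[1]
    out = {}
    for ci, cid in enumerate(component_ids):
        if not (0 <= cid < k):
            raise ValueError(f"component id {cid} out of range (k={k})")
        data = np.concatenate([maps_a[:, cid], maps_b[:, cid]])
        labels = np.array([True] * maps_a.shape[0] + [False] * maps_b.shape[0])
        pos, neg = _stats.permutation_fwe(
            data, design="two_sample", labels=labels, n_perm=n_perm,
            seed=derive_seed(seed, ci), mask=mask, **tfce_kw)
        out[int(cid)] = (pos, neg)
    return out
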