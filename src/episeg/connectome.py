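"""Parcellated time series, Fisher-z adjacency matrices, group-level
consistency of pairwise correlations, arm comparison, and sample-size
analysis.

"Robustness" of an edge at group level is the z-statistic of the one-sample
t-test on the subjects' Fisher-z correlation values for that edge: a high z
means the edge is consistently nonzero across subjects.  Arm comparisons use
a paired Wilcoxon signed-rank test over matched edges, stratified into
cortico-cortical edges and edges with at least one subcortical endpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import stats as _stats
from .synth import Volume4D

__all__ = ["ParcelTimeseries", "AdjacencyMatrix", "ConsistencyResult",
           "parcellate", "resample_to_rate", "adjacency", "group_consistency",
           "compare_arms", "sample_size_analysis"]

STRATA = ("all", "cortical", "subcortical")


@dataclass
class ParcelTimeseries:
    """Mean parcel signal per time point: (n_roi, n_t)."""

    data: np.ndarray
    roi_table: pd.DataFrame        # columns: id, name, hemisphere, klass
    dt_s: float
    flagged: list[int] = field(default_factory=list)   # parcels with <2 voxels


@dataclass
class AdjacencyMatrix:
    """Symmetric ROI x ROI Fisher-z matrix; diagonal NaN-masked."""

    z: np.ndarray
    roi_table: pd.DataFrame
    clipped: np.ndarray = None     # boolean, |r| at the clipping bound

    @property
    def n_roi(self) -> int:
        return self.z.shape[0]


@dataclass
class ConsistencyResult:
    """Edge-wise group z-stats plus per-stratum summaries."""

    zstat: np.ndarray              # (R, R) symmetric, diagonal NaN
    subject_mean: np.ndarray       # per-edge mean of subject Fisher-z
    subject_sd: np.ndarray         # per-edge SD across subjects
    n_subjects: int
    roi_table: pd.DataFrame
    summaries: dict = field(default_factory=dict)


def parcellate(vol: Volume4D, labels: np.ndarray, roi_table: pd.DataFrame,
               keep: np.ndarray | None = None) -> ParcelTimeseries:
    """Mean signal per parcel at each retained time point.

    ``roi_table`` selects and orders the parcels (air/background excluded by
    the caller).  Parcels with fewer than 2 voxels are flagged.
    """
    labels = np.asarray(labels)
    if labels.shape != vol.data.shape[:3]:
        raise ValueError("atlas shape must match the volume")
    data = vol.data
    if keep is not None:
        data = data[..., np.asarray(keep, dtype=bool)]
    out = np.empty((len(roi_table), data.shape[-1]))
    flagged = []
    for row_i, pid in enumerate(roi_table["id"].to_numpy()):
        m = labels == pid
        n_vox = int(m.sum())
        if n_vox == 0:
            out[row_i] = np.nan
            flagged.append(row_i)
            continue
        if n_vox < 2:
            flagged.append(row_i)
        out[row_i] = data[m].mean(axis=0)
    return ParcelTimeseries(data=out, roi_table=roi_table.reset_index(drop=True),
                            dt_s=vol.tr_vol_s, flagged=flagged)


def resample_to_rate(ts: ParcelTimeseries, target_dt_s: float) -> ParcelTimeseries:
    """Boxcar-average k consecutive samples so the sampling interval matches.

    Used to resample the faster single-shot series to the multishot volume
    rate before correlation, ruling out sample-count effects.  target_dt must
    be an integer multiple of the source dt.
    """
    ratio = target_dt_s / ts.dt_s
    k = int(round(ratio))
    if abs(ratio - k) > 1e-9 or k < 1:
        raise ValueError(f"target dt {target_dt_s} is not an integer multiple "
                         f"of source dt {ts.dt_s}")
    if k == 1:
        return ParcelTimeseries(ts.data.copy(), ts.roi_table, ts.dt_s,
                                list(ts.flagged))
    n = (ts.data.shape[1] // k) * k
    data = ts.data[:, :n].reshape(ts.data.shape[0], n // k, k).mean(axis=2)
    return ParcelTimeseries(data=data, roi_table=ts.roi_table,
                            dt_s=target_dt_s, flagged=list(ts.flagged))


def adjacency(ts: ParcelTimeseries, clip: float = 1.0 - 1e-7) -> AdjacencyMatrix:
    """Pairwise Pearson r, clipped and Fisher-transformed; diagonal masked.

    Zero-variance parcels have their edges set to NaN (masked).
    """
    X = ts.data
    if X.shape[1] < 8:
        raise ValueError("need at least 8 time points for adjacency")
    sd = X.std(axis=1)
    good = sd > 0
    r = np.full((X.shape[0], X.shape[0]), np.nan)
    if good.sum() >= 2:
        r_good = np.corrcoef(X[good])
        r[np.ix_(good, good)] = r_good
    clipped = np.abs(r) >= clip
    z = _stats.fisher_z(r, clip=clip)
    z[~np.isfinite(r)] = np.nan
    np.fill_diagonal(z, np.nan)
    np.fill_diagonal(clipped, False)
    return AdjacencyMatrix(z=z, roi_table=ts.roi_table,
                           clipped=np.nan_to_num(clipped).astype(bool))


def _edge_masks(roi_table: pd.DataFrame) -> dict[str, np.ndarray]:
    """Upper-triangle edge masks per stratum.

    cortical: both endpoints cortical; subcortical: >= 1 subcortical endpoint.
    """
    klass = roi_table["klass"].to_numpy()
    cort = klass == "cortical"
    sub = klass == "subcortical"
    R = len(roi_table)
    triu = np.triu(np.ones((R, R), dtype=bool), k=1)
    cc = np.outer(cort, cort) & triu
    sc = (np.outer(sub, np.ones(R, dtype=bool))
          | np.outer(np.ones(R, dtype=bool), sub)) & triu
    return {"all": triu, "cortical": cc, "subcortical": sc}


def group_consistency(mats: list[AdjacencyMatrix]) -> ConsistencyResult:
    """Edge-wise one-sample t across subjects on Fisher-z, as z-equivalents."""
    if len(mats) < 3:
        raise ValueError("need at least 3 subjects")
    R = mats[0].n_roi
    for m in mats:
        if m.n_roi != R:
            raise ValueError("subject adjacency matrices differ in size")
    stack = np.stack([m.z for m in mats])            # (n, R, R)
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    _, zstat = _stats.one_sample_t(stack, axis=0)
    zstat = np.where(np.isfinite(mean), zstat, np.nan)
    np.fill_diagonal(zstat, np.nan)

    masks = _edge_masks(mats[0].roi_table)
    summaries = {}
    for name, em in masks.items():
        vals = zstat[em]
        vals = vals[np.isfinite(vals)]
        mu, sg = float(vals.mean()), float(vals.std(ddof=1))
        summaries[name] = dict(mean_z=mu, sd_z=sg,
                               ratio=mu / sg if sg > 0 else float("inf"),
                               n_edges=int(vals.size))
    return ConsistencyResult(zstat=zstat, subject_mean=mean, subject_sd=sd,
                             n_subjects=n, roi_table=mats[0].roi_table,
                             summaries=summaries)


def compare_arms(res_a: ConsistencyResult, res_b: ConsistencyResult,
                 bins: np.ndarray | None = None) -> dict:
    """Paired Wilcoxon signed-rank over matched edges, per stratum.

    Also reports each arm's mean/SD ratio of the edge z-stat distribution
    and fixed-bin histograms for plotting.
    """
    if res_a.zstat.shape != res_b.zstat.shape:
        raise ValueError("mismatched edge sets")
    if not res_a.roi_table["id"].equals(res_b.roi_table["id"]):
        raise ValueError("ROI tables differ between arms")
    if bins is None:
        bins = np.linspace(-2.0, 10.0, 61)
    masks = _edge_masks(res_a.roi_table)
    out = {}
    for name, em in masks.items():
        xa, xb = res_a.zstat[em], res_b.zstat[em]
        ok = np.isfinite(xa) & np.isfinite(xb)
        xa, xb = xa[ok], xb[ok]
        diffs = xa - xb
        if np.allclose(diffs, 0):
            p = 1.0
        else:
            p = float(sps.wilcoxon(xa, xb, zero_method="wilcox").pvalue)
        out[name] = dict(
            p=p,
            median_diff=float(np.median(diffs)),
            ratio_a=res_a.summaries[name]["ratio"],
            ratio_b=res_b.summaries[name]["ratio"],
            n_edges=int(xa.size),
            hist_a=np.histogram(xa, bins=bins)[0].tolist(),
            hist_b=np.histogram(xb, bins=bins)[0].tolist(),
        )
    out["bins"] = bins.tolist()
    return out


def sample_size_analysis(res: ConsistencyResult, z0: float = 2.3,
                         alpha: float = 0.05, power: float = 0.8,
                         stratum: str = "subcortical") -> dict:
    """Required group size to detect the stratum's edges at threshold z0.

    Two effect-size modes are reported (the definition is not uniquely
    determined in the field):
      plain  — d = mean(subject-mean z) / mean(subject SD);
      offset — d = (mean(subject-mean z) - z0) / mean(subject SD).
    A non-positive effect size is reported as not achievable (n = None).
    """
    masks = _edge_masks(res.roi_table)
    if stratum not in masks:
        raise ValueError(f"unknown stratum {stratum!r}")
    em = masks[stratum]
    mean_e = res.subject_mean[em]
    sd_e = res.subject_sd[em]
    ok = np.isfinite(mean_e) & np.isfinite(sd_e) & (sd_e > 0)
    if not ok.any():
        raise ValueError(f"stratum {stratum!r} has no usable edges")
    mbar = float(mean_e[ok].mean())
    sbar = float(sd_e[ok].mean())
    out = dict(stratum=stratum, z0=z0, alpha=alpha, power=power,
               mean_z=mbar, mean_sd=sbar)
    for mode, d in (("plain", mbar / sbar), ("offset", (mbar - z0) / sbar)):
        if d <= 0:
            out[mode] = dict(effect_size=d, n=None, note="not achievable")
        else:
            out[mode] = dict(effect_size=d,
                             n=_stats.required_sample_size(d, alpha, power))
    return out
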