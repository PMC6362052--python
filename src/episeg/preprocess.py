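"""Temporal preprocessing: confound regression, band-pass filtering, censoring.

Applied identically to both acquisition arms.  Motion realignment and slice
timing are no-ops on the synthetic data (the generator produces no rigid-body
motion beyond spike translations); confound tables are accepted from outside
so that real data can be slotted in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as spsignal

from .synth import Volume4D

logger = logging.getLogger(__name__)

__all__ = ["regress_confounds", "bandpass", "dvars", "censor", "CensorResult"]


def _as_design(confounds) -> np.ndarray:
    if isinstance(confounds, pd.DataFrame):
        return confounds.to_numpy(dtype=float)
    return np.asarray(confounds, dtype=float)


def regress_confounds(vol: Volume4D, confounds,
                      extra_regressors: np.ndarray | None = None) -> Volume4D:
    """Voxelwise OLS residual after projecting out [intercept | confounds].

    Collinear columns are handled by a minimum-norm least-squares fit (rank
    deficiency is logged, not fatal).  The residual is orthogonal to every
    retained confound column.
    """
    conf = _as_design(confounds)
    if conf.ndim != 2 or conf.shape[0] != vol.n_t:
        raise ValueError("confound rows must match the number of volumes")
    cols = [np.ones((vol.n_t, 1)), conf]
    if extra_regressors is not None:
        extra = np.asarray(extra_regressors, dtype=float)
        if extra.ndim == 1:
            extra = extra[:, None]
        cols.append(extra)
    X = np.hstack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        logger.warning("confound design rank-deficient (rank %d of %d columns)",
                       rank, X.shape[1])
    Y = vol.data.reshape(-1, vol.n_t).T          # (t, v)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    out = resid.T.reshape(vol.data.shape)
    return vol.copy_with(out.astype(vol.data.dtype, copy=False),
                         confound_regressed=True)


def bandpass(vol: Volume4D, lo_hz: float = 0.01, hi_hz: float = 0.1,
             lp_order: int = 4) -> Volume4D:
    """Frequency-domain band-pass after linear detrending.

    Hard high-pass at lo_hz; low-pass roll-off H(f) = 2^(-(f/hi_hz)^lp_order)
    with half-amplitude exactly at hi_hz.  The default order keeps the pass
    band flat (<5% loss at hi/2) while attenuating 2*hi by >90%.
    """
    nyq = 1.0 / (2.0 * vol.tr_vol_s)
    if hi_hz >= nyq:
        raise ValueError(f"hi_hz={hi_hz} must be below Nyquist={nyq:g}")
    if not (0 < lo_hz < hi_hz):
        raise ValueError("need 0 < lo_hz < hi_hz")
    Y = vol.data.reshape(-1, vol.n_t)
    Y = spsignal.detrend(Y, axis=-1, type="linear")
    f = np.fft.rfftfreq(vol.n_t, d=vol.tr_vol_s)
    H = np.where(f >= lo_hz, np.exp2(-((f / hi_hz) ** lp_order)), 0.0)
    out = np.fft.irfft(np.fft.rfft(Y, axis=-1) * H, n=vol.n_t, axis=-1)
    return vol.copy_with(out.reshape(vol.data.shape).astype(vol.data.dtype,
                                                            copy=False),
                         band_hz=(lo_hz, hi_hz))


def dvars(vol: Volume4D, brain_mask: np.ndarray) -> np.ndarray:
    """Per-volume RMS of the backward temporal difference over brain voxels.

    Scaled by the median brain intensity of the whole series; first element 0.
    """
    mask = np.asarray(brain_mask, dtype=bool)
    if not mask.any():
        raise ValueError("brain mask is empty")
    series = vol.data[mask]                     # (v, t)
    scale = np.median(np.abs(series))
    if scale == 0:
        scale = 1.0
    diffs = np.diff(series, axis=-1)
    rms = np.sqrt(np.mean(diffs**2, axis=0)) / scale
    return np.concatenate([[0.0], rms])


@dataclass
class CensorResult:
    keep: np.ndarray            # boolean, True = retain volume
    fraction: float             # fraction of volumes censored
    threshold: float


def censor(dvars_series: np.ndarray, method: str = "iqr", k: float = 1.5,
           threshold: float | None = None) -> CensorResult:
    """Flag outlier volumes from a DVARS trace.

    Default rule: outlier iff DVARS > Q75 + k*IQR (strict, so a flat trace
    censors nothing).  An explicit ``threshold`` overrides the rule.
    """
    d = np.asarray(dvars_series, dtype=float)
    if threshold is None:
        if method != "iqr":
            raise ValueError(f"unknown censoring method {method!r}")
        q25, q75 = np.percentile(d, [25, 75])
        threshold = q75 + k * (q75 - q25)
    keep = ~(d > threshold)
    frac = float(1.0 - keep.mean())
    return CensorResult(keep=keep, fraction=frac, threshold=float(threshold))
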