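"""SNR / temporal-SNR quality metrics and their nonparametric group comparison.

tSNR is the voxelwise temporal mean divided by the temporal standard
deviation (population SD), the standard sensitivity figure of an fMRI
sequence.  ROI SNR follows the scanner convention: mean tissue signal over a
region of interest divided by the noise SD estimated in a background region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import stats as _stats
from .synth import Volume4D

__all__ = ["TsnrMap", "roi_snr", "tsnr_map", "compare_tsnr"]


@dataclass
class TsnrMap:
    """3D temporal-SNR map; invalid (zero temporal SD) voxels flagged 0."""

    data: np.ndarray
    valid: np.ndarray
    meta: dict = field(default_factory=dict)


def roi_snr(vol: Volume4D, roi: np.ndarray, background: np.ndarray) -> float:
    """Mean time-averaged ROI signal over the background noise SD.

    The noise SD pools background voxels over space and time.  SNR is scale
    invariant: rescaling the whole volume rescales numerator and denominator
    alike.
    """
    roi = np.asarray(roi, dtype=bool)
    background = np.asarray(background, dtype=bool)
    if not roi.any() or not background.any():
        raise ValueError("roi and background masks must be nonempty")
    mean_img = vol.data.mean(axis=-1)
    num = float(mean_img[roi].mean())
    noise_sd = float(vol.data[background].std(ddof=1))
    if noise_sd == 0:
        raise ValueError("background noise SD is zero (noiseless input)")
    return num / noise_sd


def tsnr_map(vol: Volume4D, mask: np.ndarray | None = None,
             keep: np.ndarray | None = None) -> TsnrMap:
    """Voxelwise mean / population-SD over uncensored volumes.

    ``keep`` restricts to uncensored time points (boolean per volume); at
    least 8 must remain.  Voxels with zero temporal SD are flagged invalid
    and set to 0.
    """
    data = vol.data
    if keep is not None:
        keep = np.asarray(keep, dtype=bool)
        if keep.shape[0] != vol.n_t:
            raise ValueError("keep mask length must equal the number of volumes")
        data = data[..., keep]
    if data.shape[-1] < 8:
        raise ValueError("need at least 8 uncensored volumes for tSNR")
    m = data.mean(axis=-1)
    sd = data.std(axis=-1, ddof=0)
    valid = sd > 0
    if mask is not None:
        valid &= np.asarray(mask, dtype=bool)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(valid, m / np.where(sd > 0, sd, 1.0), 0.0)
    return TsnrMap(data=t, valid=valid,
                   meta=dict(n_volumes=int(data.shape[-1])))


def compare_tsnr(group_a, group_b, n_perm: int = 500, seed: int = 0,
                 mask: np.ndarray | None = None, **tfce_kw):
    """Voxelwise two-sample permutation test of tSNR maps with TFCE/FWE.

    Returns both one-sided directions as
    ``{"a_gt_b": StatMap, "b_gt_a": StatMap}``.
    """
    maps_a = [m.data if isinstance(m, TsnrMap) else np.asarray(m) for m in group_a]
    maps_b = [m.data if isinstance(m, TsnrMap) else np.asarray(m) for m in group_b]
    if len(maps_a) < 3 or len(maps_b) < 3:
        raise ValueError("need at least 3 maps per group")
    shape = maps_a[0].shape
    for m in maps_a + maps_b:
        if m.shape != shape:
            raise ValueError("tSNR map shape mismatch")
    data = np.stack(maps_a + maps_b)
    labels = np.array([True] * len(maps_a) + [False] * len(maps_b))
    pos, neg = _stats.permutation_fwe(data, design="two_sample", labels=labels,
                                      n_perm=n_perm, seed=seed, mask=mask,
                                      **tfce_kw)
    return {"a_gt_b": pos, "b_gt_a": neg}
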