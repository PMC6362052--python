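"""Geometric-distortion metrics: Dice overlap, Jacobian determinants of warp
fields, and dewarping with a known off-resonance field.

No registration is estimated here.  The warp fed to the Jacobian analysis is
the known inverse-distortion field of the simulator (available by
construction), which isolates the distortion metric from any registration
algorithm.
"""

from __future__ import annotations

import numpy as np

from .synth import FieldMap, SequenceParams, Volume4D, pe_displacement, warp_pe

__all__ = ["dice", "jacobian_map", "jacobian_summary", "dewarp",
           "threshold_mask", "correction_warp"]


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice similarity 2|A∩B| / (|A|+|B|); two empty masks are an error."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    sa, sb = int(a.sum()), int(b.sum())
    if sa + sb == 0:
        raise ValueError("both masks are empty")
    return 2.0 * int((a & b).sum()) / (sa + sb)


def threshold_mask(mean_img: np.ndarray, frac: float = 0.5) -> np.ndarray:
    """Binarize a mean EPI image at ``frac`` of its robust (99th pct) maximum."""
    ref = np.percentile(mean_img, 99)
    return mean_img > frac * ref


def jacobian_map(warp: np.ndarray) -> np.ndarray:
    """det(I + ∂u/∂x) of a per-voxel displacement field (..., 3), in voxels.

    Central differences in the interior, one-sided at the boundaries
    (np.gradient).  J > 1 marks local expansion, J < 1 compression.
    """
    warp = np.asarray(warp, dtype=float)
    if warp.ndim != 4 or warp.shape[-1] != 3:
        raise ValueError("warp must have shape (X, Y, Z, 3)")
    if min(warp.shape[:3]) < 3:
        raise ValueError("each spatial dimension must be >= 3")
    G = np.empty(warp.shape[:3] + (3, 3))
    for i in range(3):
        grads = np.gradient(warp[..., i], axis=(0, 1, 2))
        for j in range(3):
            G[..., i, j] = grads[j]
    F = G + np.eye(3)
    return np.linalg.det(F)


def jacobian_summary(jmaps, brain_mask: np.ndarray | None = None,
                     delta: float = 0.05,
                     bins: np.ndarray | None = None) -> dict:
    """Pooled Jacobian histogram plus tail masses beyond 1±delta."""
    jmaps = [np.asarray(j) for j in np.atleast_1d(jmaps)] \
        if isinstance(jmaps, np.ndarray) else [np.asarray(j) for j in jmaps]
    if len(jmaps) == 0:
        raise ValueError("need at least one Jacobian map")
    vals = []
    for j in jmaps:
        v = j if brain_mask is None else j[np.asarray(brain_mask, dtype=bool)]
        vals.append(np.ravel(v))
    vals = np.concatenate(vals)
    if bins is None:
        bins = np.linspace(0.0, 2.0, 81)
    counts, edges = np.histogram(vals, bins=bins)
    return dict(
        counts=counts, edges=edges,
        tail_above=float(np.mean(vals > 1.0 + delta)),
        tail_below=float(np.mean(vals < 1.0 - delta)),
        n=int(vals.size), delta=float(delta),
    )


def correction_warp(fmap: FieldMap, seq: SequenceParams,
                    pe_axis: int = 1) -> np.ndarray:
    """Ground-truth inverse-distortion field as a (X, Y, Z, 3) displacement.

    The dewarping resampler reads the distorted image at index + shift, so
    the correction displacement equals +shift along the phase-encode axis.
    """
    shift = pe_displacement(fmap, seq, pe_axis).shift_vox
    warp = np.zeros(shift.shape + (3,))
    warp[..., pe_axis] = shift
    return warp


def dewarp(vol: Volume4D, fmap: FieldMap, seq: SequenceParams,
           pe_axis: int = 1):
    """Invert the off-resonance PE shift by resampling on the regular grid.

    Returns (corrected Volume4D, correction field (X, Y, Z, 3)) so that
    ``jacobian_map`` can consume the warp actually applied.
    """
    shift = pe_displacement(fmap, seq, pe_axis).shift_vox
    if shift.shape != vol.data.shape[:3]:
        raise ValueError("field map / volume shape mismatch")
    out = np.empty_like(vol.data)
    for t in range(vol.n_t):
        out[..., t] = warp_pe(vol.data[..., t], -shift, pe_axis)
    return vol.copy_with(out, dewarped=True), correction_warp(fmap, seq, pe_axis)
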