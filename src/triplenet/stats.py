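"""Voxelwise t-maps on subject component maps, FWE/FDR control, clusters.

One-sample t-maps (per group) define the network regions of interest;
two-sample t-maps locate within-network group differences.  Family-wise
error control is Bonferroni over in-mask voxels; false-discovery-rate
control is Benjamini-Hochberg.  Suprathreshold masks are reported as
connected-component cluster tables with peak coordinates in millimetres.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatMap",
    "one_sample_tmap",
    "two_sample_tmap",
    "threshold_fdr",
    "threshold_fwe",
    "cluster_report",
]

log = logging.getLogger(__name__)


@dataclass
class StatMap:
    """A thresholded voxelwise t-map on a 3D grid."""

    t_values: np.ndarray  # 3D
    dof: int
    p_values: np.ndarray  # 3D, two-sided
    threshold_kind: str  # "FWE" | "FDR" | "none"
    alpha: float
    suprathreshold_mask: np.ndarray  # 3D boolean (union of signs)
    mask_pos: np.ndarray | None = None  # t > 0 suprathreshold (A > B)
    mask_neg: np.ndarray | None = None  # t < 0 suprathreshold (B > A)
    n_zero_variance: int = 0


def threshold_fwe(p_values, alpha: float):
    """Bonferroni: reject p_i <= alpha / m.  Returns a boolean array."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    return p <= alpha / p.size


def threshold_fdr(p_values, q: float):
    """Benjamini-Hochberg step-up rejections.  Returns a boolean array."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def _apply_correction(p_flat, valid, alpha, correction):
    """Reject over the valid (non-degenerate) voxels only."""
    rejected = np.zeros(p_flat.size, dtype=bool)
    if correction.upper() == "FWE":
        rejected[valid] = threshold_fwe(p_flat[valid], alpha)
    elif correction.upper() == "FDR":
        rejected[valid] = threshold_fdr(p_flat[valid], alpha)
    elif correction.lower() == "none":
        rejected[valid] = p_flat[valid] <= alpha
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return rejected


def _unflatten(flat, mask, fill=0.0):
    out = np.full(mask.shape, fill, dtype=float)
    out[mask] = flat
    return out


def one_sample_tmap(subject_maps: np.ndarray, mask: np.ndarray,
                    alpha: float = 0.001, correction: str = "FWE") -> StatMap:
    """Voxelwise one-sample t-test of subject maps against zero.

    ``subject_maps`` is (subjects x in-mask voxels).  The suprathreshold
    mask (corrected p below ``alpha`` and t > 0) is the network ROI.
    Zero-variance voxels get t = 0 and are excluded from the correction.
    """
    maps = np.asarray(subject_maps, dtype=float)
    n = maps.shape[0]
    if n < 3:
        raise ValueError("one-sample t-map needs at least 3 subjects")
    mean = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=1)
    valid = sd > 0
    n_zero = int((~valid).sum())
    if n_zero:
        log.info("one_sample_tmap: %d zero-variance voxels excluded", n_zero)
    t = np.zeros_like(mean)
    t[valid] = mean[valid] / (sd[valid] / np.sqrt(n))
    dof = n - 1
    p = np.ones_like(t)
    p[valid] = 2.0 * sps.t.sf(np.abs(t[valid]), dof)
    rejected = _apply_correction(p, valid, alpha, correction)
    supra = rejected & (t > 0)
    return StatMap(
        t_values=_unflatten(t, mask),
        dof=dof,
        p_values=_unflatten(p, mask, fill=1.0),
        threshold_kind=correction.upper() if correction.lower() != "none" else "none",
        alpha=alpha,
        suprathreshold_mask=_unflatten(supra, mask).astype(bool),
        mask_pos=_unflatten(supra, mask).astype(bool),
        mask_neg=_unflatten(rejected & (t < 0), mask).astype(bool),
        n_zero_variance=n_zero,
    )


def two_sample_tmap(group_a_maps: np.ndarray, group_b_maps: np.ndarray,
                    mask: np.ndarray, alpha: float = 0.05,
                    correction: str = "FDR",
                    restrict: np.ndarray | None = None) -> StatMap:
    """Pooled-variance two-sample t-test per voxel (A minus B).

    Two-sided p-values; the positive and negative suprathreshold masks
    (A > B and B > A) are reported separately.  ``restrict`` optionally
    limits testing (and the multiplicity correction) to a boolean subset of
    the in-mask voxels.
    """
    a = np.asarray(group_a_maps, dtype=float)
    b = np.asarray(group_b_maps, dtype=float)
    na, nb = a.shape[0], b.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 subjects")
    dof = na + nb - 2
    pooled_var = ((na - 1) * a.var(axis=0, ddof=1) +
                  (nb - 1) * b.var(axis=0, ddof=1)) / dof
    se = np.sqrt(pooled_var * (1.0 / na + 1.0 / nb))
    valid = se > 0
    if restrict is not None:
        valid &= np.asarray(restrict, dtype=bool)
    n_zero = int((se <= 0).sum())
    t = np.zeros(a.shape[1])
    t[valid] = (a.mean(axis=0) - b.mean(axis=0))[valid] / se[valid]
    p = np.ones_like(t)
    p[valid] = 2.0 * sps.t.sf(np.abs(t[valid]), dof)
    rejected = _apply_correction(p, valid, alpha, correction)
    return StatMap(
        t_values=_unflatten(t, mask),
        dof=dof,
        p_values=_unflatten(p, mask, fill=1.0),
        threshold_kind=correction.upper() if correction.lower() != "none" else "none",
        alpha=alpha,
        suprathreshold_mask=_unflatten(rejected, mask).astype(bool),
        mask_pos=_unflatten(rejected & (t > 0), mask).astype(bool),
        mask_neg=_unflatten(rejected & (t < 0), mask).astype(bool),
        n_zero_variance=n_zero,
    )


_CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=int)


def cluster_report(stat_map: StatMap, affine: np.ndarray,
                   min_extent: int = 10,
                   sign_labels: tuple = ("A>B", "B>A")) -> pd.DataFrame:
    """Connected-component cluster table of a thresholded map.

    26-connectivity components of the positive and negative suprathreshold
    masks; per cluster the voxel count and the location of the peak |t|
    mapped to millimetres through the affine.  Clusters smaller than
    ``min_extent`` are dropped; rows are sorted by peak |t| descending.
    """
    rows = []
    for sign_mask, label in ((stat_map.mask_pos, sign_labels[0]),
                             (stat_map.mask_neg, sign_labels[1])):
        if sign_mask is None or not sign_mask.any():
            continue
        labelled, n_clusters = ndimage.label(sign_mask, structure=_CONNECTIVITY_26)
        for c in range(1, n_clusters + 1):
            in_cluster = labelled == c
            n_vox = int(in_cluster.sum())
            if n_vox < min_extent:
                continue
            t_abs = np.where(in_cluster, np.abs(stat_map.t_values), -np.inf)
            peak_idx = np.unravel_index(np.argmax(t_abs), t_abs.shape)
            peak_mm = affine @ np.array([*peak_idx, 1.0])
            rows.append({
                "sign": label,
                "peak_t": float(stat_map.t_values[peak_idx]),
                "x_mm": float(peak_mm[0]),
                "y_mm": float(peak_mm[1]),
                "z_mm": float(peak_mm[2]),
                "n_voxels": n_vox,
            })
    table = pd.DataFrame(rows, columns=["sign", "peak_t", "x_mm", "y_mm",
                                        "z_mm", "n_voxels"])
    if len(table):
        table = table.reindex(
            table.peak_t.abs().sort_values(ascending=False).index
        ).reset_index(drop=True)
    return table
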