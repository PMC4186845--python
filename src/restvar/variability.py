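"""Voxelwise BOLD signal variability and its across-subject relation to
behavioral scores.

Variability is the per-voxel standard deviation of the percent-change BOLD
series (population formula, ddof=0, by default; with several hundred frames
the sample/population distinction is negligible, and the choice is carried
in the map metadata).  The brain-behavior statistic is the across-subject
Pearson correlation of the per-voxel metric with the scores, with a
two-tailed p-value from t = r*sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom
— identical to the slope t-test of a simple linear regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .preprocess import PercentChangeSeries


@dataclass
class VariabilityMap:
    """Per-voxel SD of the percent-change series (percent units)."""

    sd: np.ndarray
    mask: np.ndarray
    subject_id: str
    ddof: int = 0


@dataclass
class CohortStatMap:
    """Across-subject Pearson r and two-tailed p per voxel.

    p is consistent with a two-tailed t-test at df = n_subjects - 2.
    Voxels where the metric has zero variance across subjects carry NaN.
    """

    r: np.ndarray
    p: np.ndarray
    mask: np.ndarray
    n_subjects: int
    metric_name: str


def voxel_sd(pc: PercentChangeSeries, ddof: int = 0, subject_id: str = "") -> VariabilityMap:
    """Per-voxel temporal SD of a percent-change series; zero outside mask."""
    if pc.n_timepoints < 2:
        raise ValueError("need at least 2 timepoints for an SD")
    sd = np.zeros(pc.data.shape[:3])
    sd[pc.mask] = pc.data[pc.mask].std(axis=-1, ddof=ddof)
    return VariabilityMap(sd=sd, mask=pc.mask.copy(), subject_id=subject_id, ddof=ddof)


def correlate_with_scores(values, scores) -> tuple[float, float]:
    """Pearson r and two-tailed p of per-subject values against scores."""
    values = np.asarray(values, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if values.shape != scores.shape or values.ndim != 1:
        raise ValueError("values and scores must be equal-length 1D arrays")
    if values.size < 3:
        raise ValueError("need at least 3 subjects")
    if np.any(np.isnan(values)) or np.any(np.isnan(scores)):
        raise ValueError("missing values are not allowed")
    if values.std() == 0 or scores.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    res = stats.pearsonr(values, scores)
    return float(res.statistic), float(res.pvalue)


def pearson_map(values: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized across-subject Pearson r and two-tailed p.

    ``values`` is S x V (subjects by voxels).  Zero-variance columns give
    NaN in both outputs.
    """
    values = np.asarray(values, dtype=float)
    scores = np.asarray(scores, dtype=float)
    n = values.shape[0]
    vc = values - values.mean(axis=0)
    sc = scores - scores.mean()
    denom = np.sqrt((vc**2).sum(axis=0)) * np.sqrt((sc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (vc * sc[:, None]).sum(axis=0) / denom, np.nan)
        r = np.clip(r, -1.0, 1.0)
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, np.finfo(float).tiny))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isnan(r)] = np.nan
    return r, p


def _cohort_map(
    stack: np.ndarray, masks: list[np.ndarray], scores, n: int, metric_name: str
) -> CohortStatMap:
    mask = np.logical_and.reduce(masks)
    scores = np.asarray(scores, dtype=float)
    r_flat, p_flat = pearson_map(stack[:, mask], scores)
    r = np.zeros(mask.shape)
    p = np.ones(mask.shape)
    r[mask] = r_flat
    p[mask] = p_flat
    # degenerate voxels (zero variance across subjects) drop out of the mask
    bad = mask.copy()
    bad[mask] = np.isnan(r_flat)
    mask = mask & ~bad
    r[bad] = 0.0
    p[bad] = 1.0
    return CohortStatMap(r=r, p=p, mask=mask, n_subjects=n, metric_name=metric_name)


def cohort_variability_map(maps: list[VariabilityMap], scores) -> CohortStatMap:
    """Voxelwise SD-vs-score correlation over subjects, in the intersection
    of the subject masks."""
    if len(maps) != len(np.asarray(scores)):
        raise ValueError("one score per variability map required")
    ids = [m.subject_id for m in maps]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject ids")
    grid = maps[0].sd.shape
    if any(m.sd.shape != grid for m in maps):
        raise ValueError("variability maps are on different grids")
    stack = np.stack([m.sd for m in maps])
    return _cohort_map(
        stack, [m.mask for m in maps], scores, len(maps), "bold_sd_vs_score"
    )


def cluster_average_sd(
    pc: PercentChangeSeries, cluster_mask: np.ndarray, ddof: int = 0
) -> float:
    """SD of the spatially averaged percent-change course within a cluster.

    Averaging before taking the SD discounts spatially incoherent variance,
    so this is at most the mean of the voxelwise SDs.
    """
    sel = np.asarray(cluster_mask, dtype=bool) & pc.mask
    if not sel.any():
        raise ValueError("cluster is empty within the analysis mask")
    return float(pc.data[sel].mean(axis=0).std(ddof=ddof))
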