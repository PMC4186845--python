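"""Seed-based functional connectivity and its across-subject relation to
behavioral scores.

For each seed parcel the BOLD percent-change courses are averaged over the
parcel, correlated with every brain voxel, and the correlation map is
variance-stabilized with the Fisher transform z = atanh(r).  Across
subjects, z at each voxel is then correlated with the behavioral scores
(same Pearson/t machinery as the variability analysis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import PercentChangeSeries
from .variability import CohortStatMap, _cohort_map

#: |r| is clipped here before atanh so saturated correlations stay finite
R_CLIP = 1.0 - 1e-7


@dataclass(frozen=True)
class SeedDefinition:
    """An anatomical parcel used as a connectivity seed."""

    label_id: int
    label_name: str
    side: str
    voxel_count: int


@dataclass
class ConnectivityMap:
    """One subject's seed correlation map and its Fisher transform."""

    r: np.ndarray
    z: np.ndarray
    mask: np.ndarray
    seed: SeedDefinition
    subject_id: str


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Fisher z = atanh(r), with |r| clipped to 1 - 1e-7."""
    return np.arctanh(np.clip(r, -R_CLIP, R_CLIP))


def seeds_from_parcellation(
    parcellation: np.ndarray,
    labels: dict[int, tuple[str, str]],
    mask: np.ndarray | None = None,
) -> list[SeedDefinition]:
    """One SeedDefinition per parcel label present in the (masked) volume."""
    seeds = []
    parc = np.asarray(parcellation)
    if mask is not None:
        parc = np.where(np.asarray(mask, dtype=bool), parc, 0)
    for label, (name, side) in sorted(labels.items()):
        count = int((parc == label).sum())
        if count >= 1:
            seeds.append(SeedDefinition(label, name, side, count))
    return seeds


def roi_mean_timeseries(pc: PercentChangeSeries, roi_mask: np.ndarray) -> np.ndarray:
    """Unweighted mean percent-change course over ROI-and-analysis-mask voxels."""
    sel = np.asarray(roi_mask, dtype=bool) & pc.mask
    if not sel.any():
        raise ValueError("ROI does not intersect the analysis mask")
    return pc.data[sel].mean(axis=0)


def seed_correlation_map(
    pc: PercentChangeSeries,
    seed_ts: np.ndarray,
    seed: SeedDefinition | None = None,
    subject_id: str = "",
) -> ConnectivityMap:
    """Pearson r of every masked voxel with the seed course, plus Fisher z."""
    seed_ts = np.asarray(seed_ts, dtype=float)
    sc = seed_ts - seed_ts.mean()
    seed_norm = np.sqrt((sc**2).sum())
    if seed_norm == 0:
        raise ValueError("seed time course is constant")
    vox = pc.data[pc.mask]  # V x T
    vc = vox - vox.mean(axis=-1, keepdims=True)
    denom = np.sqrt((vc**2).sum(axis=-1)) * seed_norm
    with np.errstate(invalid="ignore", divide="ignore"):
        r_flat = np.where(denom > 0, vc @ sc / denom, 0.0)
    r_flat = np.clip(r_flat, -1.0, 1.0)
    r = np.zeros(pc.data.shape[:3])
    r[pc.mask] = r_flat
    z = np.zeros_like(r)
    z[pc.mask] = fisher_z(r_flat)
    if seed is None:
        seed = SeedDefinition(0, "custom", "L", 1)
    return ConnectivityMap(r=r, z=z, mask=pc.mask.copy(), seed=seed, subject_id=subject_id)


def cohort_connectivity_map(maps: list[ConnectivityMap], scores) -> CohortStatMap:
    """Voxelwise across-subject correlation of Fisher z with the scores."""
    if len(maps) != len(np.asarray(scores)):
        raise ValueError("one score per connectivity map required")
    seeds = {m.seed.label_id for m in maps}
    if len(seeds) != 1:
        raise ValueError("all maps must share one seed")
    stack = np.stack([m.z for m in maps])
    name = f"fc_z_seed{maps[0].seed.label_id}_vs_score"
    return _cohort_map(stack, [m.mask for m in maps], scores, len(maps), name)
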