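"""End-to-end orchestration: manifest in, statistic maps and cluster tables out.

A cohort lives on disk as a TSV manifest (one row per subject: id, score,
semicolon-joined run and motion paths, mask and PV-map paths) next to a
parcellation volume and label table — the layout :func:`restvar.cohort.save_cohort`
writes.  ``run_variability_analysis`` and ``run_connectivity_analysis``
load it, preprocess every subject, compute the cohort statistic map(s), run
the Monte-Carlo cluster correction, and write NIfTI maps, TSV cluster
tables, a motion-confound report and a YAML provenance file echoing every
parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import cluster as clu
from . import connectivity as conn
from . import preprocess as pre
from . import variability as var
from .connectivity import SeedDefinition


class PipelineError(RuntimeError):
    """Raised for missing inputs or malformed manifests."""


@dataclass
class RunConfig:
    """All pipeline parameters; defaults mirror the default processing
    stream (5 discarded frames, 3 mm FWHM, 0.99 PV threshold, 2-voxel
    erosions, 50 mm head radius, alpha 0.05, 1000 null iterations, no
    low-pass filter)."""

    manifest: str
    parcellation: str
    labels: str
    out_dir: str
    n_discard: int = 5
    fwhm: float = 3.0
    pv_threshold: float = 0.99
    erosions: int = 2
    mask_erosion_2d: int = 2
    head_radius: float = 50.0
    rotation_unit: str = "degrees"
    voxel_p: float = 0.05
    alpha: float = 0.05
    n_iter: int = 1000
    connectivity_rule: str = "faces"
    orientation: str = "LPS"
    lowpass: bool = False
    sd_ddof: int = 0
    split_sign: bool = True
    seed: int = 0
    extra: dict = field(default_factory=dict)


@dataclass
class SubjectData:
    subject_id: str
    pc: pre.PercentChangeSeries
    fd_mean: float
    score: float


def _require(path: str | Path) -> Path:
    p = Path(path)
    if not p.exists():
        raise PipelineError(f"missing input file: {p}")
    return p


def _load_nii(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(_require(path))
    return np.asarray(img.dataobj), img.affine


def load_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(_require(path), sep="\t")
    required = {"subject_id", "score", "runs", "motion", "mask", "wm_pv", "csf_pv"}
    missing = required - set(df.columns)
    if missing:
        raise PipelineError(f"manifest is missing columns: {sorted(missing)}")
    if len(df) < 3:
        raise PipelineError("manifest must list at least 3 subjects")
    return df


def preprocess_subject_row(row: pd.Series, config: RunConfig) -> SubjectData:
    """Preprocess one manifest row into a concatenated percent-change series."""
    run_paths = str(row["runs"]).split(";")
    motion_paths = str(row["motion"]).split(";")
    if len(run_paths) != len(motion_paths):
        raise PipelineError(f"{row['subject_id']}: run/motion path count mismatch")

    mask_arr, affine = _load_nii(row["mask"])
    brain = pre.erode_mask_2d(mask_arr > 0, config.mask_erosion_2d)
    voxel_size = float(np.abs(np.linalg.det(affine[:3, :3])) ** (1.0 / 3.0))
    wm_pv, _ = _load_nii(row["wm_pv"])
    csf_pv, _ = _load_nii(row["csf_pv"])
    wm_region, wm_empty = pre.tissue_region(wm_pv, config.pv_threshold, config.erosions)
    csf_region, csf_empty = pre.tissue_region(
        csf_pv, config.pv_threshold, config.erosions
    )
    if wm_empty or csf_empty:
        raise PipelineError(
            f"{row['subject_id']}: empty WM/CSF nuisance region after erosion"
        )

    pcs, fd_means = [], []
    for rp, mp in zip(run_paths, motion_paths):
        img = nib.load(_require(rp))
        run = np.asarray(img.dataobj, dtype=float)
        tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 2.0
        motion = np.loadtxt(_require(mp))
        fd_means.append(
            pre.framewise_displacement(
                motion, config.head_radius, config.rotation_unit
            ).mean_fd
        )
        pcs.append(
            pre.preprocess_run(
                run,
                motion,
                brain,
                wm_region,
                csf_region,
                tr=tr,
                voxel_size=voxel_size,
                n_discard=config.n_discard,
                fwhm=config.fwhm,
                lowpass=config.lowpass,
            )
        )
    return SubjectData(
        subject_id=str(row["subject_id"]),
        pc=pre.concatenate_runs(pcs),
        fd_mean=float(np.mean(fd_means)),
        score=float(row["score"]),
    )


def preprocess_record(
    sub,
    n_discard: int = 5,
    fwhm: float = 3.0,
    pv_threshold: float = 0.99,
    erosions: int = 2,
    mask_erosion_2d: int = 2,
    head_radius: float = 50.0,
    lowpass: bool = False,
) -> SubjectData:
    """Preprocess an in-memory :class:`restvar.cohort.SubjectRecord`.

    Same stream as :func:`preprocess_subject_row` without the disk round
    trip; used by the analysis drivers and simulation studies.
    """
    voxel_size = float(np.abs(np.linalg.det(sub.affine[:3, :3])) ** (1.0 / 3.0))
    brain = pre.erode_mask_2d(sub.brain_mask, mask_erosion_2d)
    wm_region, wm_empty = pre.tissue_region(sub.pv_maps["wm"], pv_threshold, erosions)
    csf_region, csf_empty = pre.tissue_region(
        sub.pv_maps["csf"], pv_threshold, erosions
    )
    if wm_empty or csf_empty:
        raise PipelineError(f"{sub.subject_id}: empty WM/CSF nuisance region")
    pcs, fd_means = [], []
    for run, motion in zip(sub.runs, sub.motion):
        fd_means.append(
            pre.framewise_displacement(motion, head_radius, sub.rotation_unit).mean_fd
        )
        pcs.append(
            pre.preprocess_run(
                run, motion, brain, wm_region, csf_region,
                tr=sub.tr, voxel_size=voxel_size,
                n_discard=n_discard, fwhm=fwhm, lowpass=lowpass,
            )
        )
    return SubjectData(
        subject_id=sub.subject_id,
        pc=pre.concatenate_runs(pcs),
        fd_mean=float(np.mean(fd_means)),
        score=sub.score,
    )


def load_and_preprocess(config: RunConfig) -> list[SubjectData]:
    df = load_manifest(config.manifest)
    if df["subject_id"].duplicated().any():
        raise PipelineError("duplicate subject ids in manifest")
    return [preprocess_subject_row(row, config) for _, row in df.iterrows()]


def _load_labels(path: str | Path) -> dict[int, tuple[str, str]]:
    df = pd.read_csv(_require(path), sep="\t")
    return {
        int(r["label"]): (str(r["name"]), str(r["side"])) for _, r in df.iterrows()
    }


def _write_stat_maps(
    stat: var.CohortStatMap, affine: np.ndarray, outdir: Path, prefix: str
) -> None:
    nib.save(nib.Nifti1Image(stat.r.astype(np.float32), affine), outdir / f"{prefix}_r.nii.gz")
    nib.save(nib.Nifti1Image(stat.p.astype(np.float32), affine), outdir / f"{prefix}_p.nii.gz")


def _provenance(config: RunConfig, outdir: Path, extra: dict) -> None:
    payload = asdict(config)
    payload.update(extra)
    with open(outdir / "provenance.yaml", "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def _cluster_stage(
    stat: var.CohortStatMap,
    config: RunConfig,
    parcellation: np.ndarray,
    labels: dict[int, tuple[str, str]],
    affine: np.ndarray,
    voxel_size: float,
    null_dist: clu.NullClusterDistribution | None = None,
) -> tuple[clu.ClusterReport, clu.NullClusterDistribution, int]:
    if null_dist is None:
        null_dist = clu.simulate_null_distribution(
            stat.mask,
            fwhm=config.fwhm,
            voxel_size=voxel_size,
            voxel_p=config.voxel_p,
            n_iter=config.n_iter,
            connectivity_rule=config.connectivity_rule,
            seed=config.seed + 1_000_003,
        )
    k_min = clu.min_cluster_size(null_dist, config.alpha)
    clusters = clu.extract_clusters(
        stat, config.voxel_p, k_min, config.connectivity_rule, config.split_sign
    )
    report = clu.report_clusters(
        clusters, stat, parcellation, labels, affine, config.orientation, k_min
    )
    return report, null_dist, k_min


def run_variability_analysis(
    config: RunConfig, subjects: list[SubjectData] | None = None
) -> tuple[var.CohortStatMap, clu.ClusterReport]:
    """Variability arm: SD maps -> cohort r/p map -> cluster table + files."""
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    parc, affine = _load_nii(config.parcellation)
    labels = _load_labels(config.labels)
    voxel_size = float(np.abs(np.linalg.det(affine[:3, :3])) ** (1.0 / 3.0))

    if subjects is None:
        subjects = load_and_preprocess(config)
    scores = np.array([s.score for s in subjects])
    sd_maps = [
        var.voxel_sd(s.pc, ddof=config.sd_ddof, subject_id=s.subject_id)
        for s in subjects
    ]
    stat = var.cohort_variability_map(sd_maps, scores)
    report, null_dist, k_min = _cluster_stage(
        stat, config, parc, labels, affine, voxel_size
    )

    fd_r, fd_p = var.correlate_with_scores(
        np.array([s.fd_mean for s in subjects]), scores
    )
    _write_stat_maps(stat, affine, outdir, "variability")
    report.table.to_csv(outdir / "variability_clusters.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"metric": "mean_fd_vs_score_r", "value": fd_r},
         {"metric": "mean_fd_vs_score_p", "value": fd_p}]
    ).to_csv(outdir / "motion_confound.tsv", sep="\t", index=False)
    _provenance(
        config, outdir,
        {"k_min": k_min, "null_n_iter": null_dist.n_iter,
         "motion_confound_r": float(fd_r), "motion_confound_p": float(fd_p)},
    )
    return stat, report


def run_connectivity_analysis(
    config: RunConfig,
    seeds: list[SeedDefinition],
    subjects: list[SubjectData] | None = None,
) -> dict[int, tuple[var.CohortStatMap, clu.ClusterReport]]:
    """Connectivity arm, one statistic map and cluster table per seed.

    A summary TSV lists which seeds produced surviving clusters.  Returns
    ``{seed label: (stat map, report)}``.
    """
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    parc, affine = _load_nii(config.parcellation)
    labels = _load_labels(config.labels)
    voxel_size = float(np.abs(np.linalg.det(affine[:3, :3])) ** (1.0 / 3.0))
    if not seeds:
        import warnings

        warnings.warn("empty seed list: nothing to do", stacklevel=2)
        return {}
    for seed in seeds:
        if not np.any(parc == seed.label_id):
            raise PipelineError(f"seed label {seed.label_id} absent from parcellation")

    if subjects is None:
        subjects = load_and_preprocess(config)
    scores = np.array([s.score for s in subjects])

    results: dict[int, tuple[var.CohortStatMap, clu.ClusterReport]] = {}
    summary_rows = []
    null_dist: clu.NullClusterDistribution | None = None
    for seed in seeds:
        roi = parc == seed.label_id
        maps = []
        for s in subjects:
            seed_ts = conn.roi_mean_timeseries(s.pc, roi)
            maps.append(
                conn.seed_correlation_map(s.pc, seed_ts, seed, s.subject_id)
            )
        stat = conn.cohort_connectivity_map(maps, scores)
        report, null_dist, k_min = _cluster_stage(
            stat, config, parc, labels, affine, voxel_size, null_dist
        )
        prefix = f"fc_seed{seed.label_id:02d}"
        _write_stat_maps(stat, affine, outdir, prefix)
        report.table.to_csv(outdir / f"{prefix}_clusters.tsv", sep="\t", index=False)
        summary_rows.append(
            {
                "seed_label": seed.label_id,
                "seed_name": seed.label_name,
                "seed_side": seed.side,
                "n_surviving_clusters": len(report.table),
            }
        )
        results[seed.label_id] = (stat, report)
    pd.DataFrame(summary_rows).to_csv(
        outdir / "connectivity_summary.tsv", sep="\t", index=False
    )
    _provenance(config, outdir, {"k_min": k_min, "n_seeds": len(seeds)})
    return results
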