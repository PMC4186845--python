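"""Synthetic multi-subject resting-state fMRI cohort generator.

Emulates the statistical structure the downstream analysis assumes, so the
whole pipeline is testable without access to scanner data:

* voxel noise with AR(1) temporal autocorrelation and Gaussian spatial
  smoothness (white innovations smoothed at a configurable FWHM, then
  restandardized within the brain mask so the null field matches the
  cluster-null simulator's assumption);
* per-subject behavioral scores drawn uniformly over a configurable range
  (default 76-96 % correct, the span seen in small resting-state cohorts of
  this kind);
* "variability" effects: within chosen parcels the per-subject signal SD is
  an affine function of the score plus calibrated jitter, so the
  across-subject SD-vs-score Pearson r approaches a configured target;
* "connectivity" effects: a shared latent time course injected into a seed
  and a target parcel with target amplitude increasing linearly in score;
* rigid-body motion traces (random walk) rescaled so the Power-formula mean
  framewise displacement hits an exact per-subject target.

Everything is deterministic given ``CohortConfig.seed``; subject- and
run-level streams are spawned from one root ``SeedSequence``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from .preprocess import FWHM_TO_SIGMA, framewise_displacement

#: raw-signal baseline (arbitrary scanner units)
BASELINE = 1000.0
#: baseline fluctuation amplitude, percent of the baseline
BASE_SIGMA_PCT = 1.0
#: fractional SD modulation amplitude for variability effects
EFFECT_AMPLITUDE = 0.25
#: latent-coupling amplitude injected into the seed parcel
SEED_COUPLING = 0.3

#: default parcel layout: label -> (name, side, center as grid fractions, radius mm)
DEFAULT_PARCELS: dict[int, tuple[str, str, tuple[float, float, float], float]] = {
    1: ("caudate", "L", (0.62, 0.50, 0.45), 5.0),
    2: ("caudate", "R", (0.38, 0.50, 0.45), 5.0),
    3: ("putamen", "L", (0.70, 0.45, 0.40), 6.0),
    4: ("putamen", "R", (0.30, 0.45, 0.40), 6.0),
    5: ("hippocampus", "L", (0.66, 0.62, 0.30), 6.0),
    6: ("fusiform", "R", (0.32, 0.70, 0.25), 7.0),
    7: ("superior_temporal", "R", (0.25, 0.55, 0.35), 7.0),
    8: ("thalamus", "L", (0.56, 0.55, 0.48), 5.0),
}


class CohortConfigError(ValueError):
    """Raised for invalid cohort configurations."""


@dataclass
class CohortConfig:
    """Study-scale defaults: 10 subjects, two 8-minute runs at TR 2 s on a
    48x56x40 grid of 2 mm voxels, AR(1) coefficient 0.4, 3 mm smoothness,
    scores uniform on [76, 96] %, mean FD uniform on [0.06, 0.11] mm.

    ``effect_rois`` lists (parcel label, target across-subject r) pairs for
    variability effects; ``connectivity_effect`` is (seed label, target
    label, coupling slope per score percent) or None.
    """

    n_subjects: int = 10
    grid_shape: tuple[int, int, int] = (48, 56, 40)
    voxel_size: float = 2.0
    n_runs: int = 2
    n_timepoints_per_run: int = 240
    tr: float = 2.0
    ar1_coeff: float = 0.4
    spatial_fwhm: float = 3.0
    effect_rois: tuple[tuple[int, float], ...] = ()
    connectivity_effect: tuple[int, int, float] | None = None
    score_range: tuple[float, float] = (76.0, 96.0)
    mean_fd_range: tuple[float, float] = (0.06, 0.11)
    seed: int = 0

    # frames the downstream pipeline will discard + nuisance regressors
    _min_timepoints: int = field(default=5 + 19, repr=False)

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise CohortConfigError("n_subjects must be >= 1")
        if self.n_timepoints_per_run <= self._min_timepoints:
            raise CohortConfigError(
                f"n_timepoints_per_run must exceed {self._min_timepoints} "
                "(discarded frames + nuisance regressors)"
            )
        if not 0 <= abs(self.ar1_coeff) < 1:
            raise CohortConfigError("|ar1_coeff| must be < 1")
        lo, hi = self.score_range
        if not (0 <= lo <= hi <= 100):
            raise CohortConfigError("score_range must lie within [0, 100]")
        for label, r in self.effect_rois:
            if not -1 < r < 1:
                raise CohortConfigError(f"target r={r} for label {label} not in (-1, 1)")


@dataclass
class SubjectRecord:
    """One subject: raw 4D runs, motion traces, masks, PV maps and score.

    Rotational motion parameters are in degrees (AFNI convention); the unit
    travels with the record in ``rotation_unit``.
    """

    subject_id: str
    runs: list[np.ndarray]
    motion: list[np.ndarray]
    brain_mask: np.ndarray
    pv_maps: dict[str, np.ndarray]
    score: float
    affine: np.ndarray
    tr: float
    rotation_unit: str = "degrees"


@dataclass
class Cohort:
    """Generated subjects plus the shared anatomy (mask, parcellation)."""

    subjects: list[SubjectRecord]
    parcellation: np.ndarray
    labels: dict[int, tuple[str, str]]  # label -> (name, side)
    affine: np.ndarray
    config: CohortConfig

    def __iter__(self):
        return iter(self.subjects)

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def scores(self) -> np.ndarray:
        return np.array([s.score for s in self.subjects])


def score_recall(truth: list, judgments: list) -> float:
    """Percent of correct same/moved judgments: 100 * matches / items."""
    if len(truth) == 0 or len(truth) != len(judgments):
        raise ValueError("truth and judgments must be equal-length and nonempty")
    matches = sum(t == j for t, j in zip(truth, judgments))
    return 100.0 * matches / len(truth)


def generate_motion(
    n_timepoints: int,
    target_mean_fd: float,
    seed: int | np.random.SeedSequence,
    rotation_unit: str = "degrees",
    head_radius: float = 50.0,
) -> np.ndarray:
    """Random-walk T x 6 motion trace with an exact Power-formula mean FD.

    A Gaussian random walk is generated for each parameter and then rescaled
    (about its initial value) so the mean framewise displacement equals
    ``target_mean_fd``; FD is linear in the increments, so the match is exact
    to floating point.  ``target_mean_fd = 0`` yields a constant trace.
    """
    if n_timepoints < 2:
        raise ValueError("need at least 2 timepoints for a motion trace")
    if target_mean_fd < 0:
        raise ValueError("target_mean_fd must be >= 0")
    rng = np.random.default_rng(seed)
    increments = rng.normal(0.0, 0.01, size=(n_timepoints - 1, 6))
    start = rng.normal(0.0, 0.05, size=(1, 6))
    trace = np.vstack([start, start + np.cumsum(increments, axis=0)])
    current = framewise_displacement(
        trace, head_radius=head_radius, rotation_unit=rotation_unit
    ).mean_fd
    scale = 0.0 if target_mean_fd == 0 else target_mean_fd / current
    return start + (trace - start) * scale


def build_anatomy(
    grid_shape: tuple[int, int, int], voxel_size: float
) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray], dict[int, tuple[str, str]]]:
    """Deterministic brain mask, parcellation and tissue PV maps for a grid.

    The brain is an ellipsoid filling ~80% of the grid; parcels are spheres
    at fixed fractional positions (left hemisphere at high x index, matching
    a +x-left world axis); CSF is a central ventricle-like box and WM a
    deep box beside it, both thick enough to survive 2-voxel 3D erosion.
    Returns (brain_mask, parcellation, pv_maps, labels).
    """
    nx, ny, nz = grid_shape
    idx = np.indices(grid_shape, dtype=float)
    center = (np.array(grid_shape) - 1) / 2.0
    semi = np.array(grid_shape) * 0.45
    brain = (
        ((idx[0] - center[0]) / semi[0]) ** 2
        + ((idx[1] - center[1]) / semi[1]) ** 2
        + ((idx[2] - center[2]) / semi[2]) ** 2
    ) <= 1.0

    def _box(center_frac: tuple[float, float, float], half: int) -> np.ndarray:
        c = (np.array(center_frac) * (np.array(grid_shape) - 1)).round().astype(int)
        box = np.zeros(grid_shape, dtype=bool)
        sl = tuple(
            slice(max(ci - half, 0), min(ci + half + 1, n))
            for ci, n in zip(c, grid_shape)
        )
        box[sl] = True
        return box & brain

    # tissue boxes are placed first (superior, away from the parcels) with
    # half-widths >= 3 so a 2-voxel 3D erosion leaves a core on small grids
    half = max(3, min(nx, ny, nz) // 8)
    csf = _box((0.38, 0.5, 0.72), half)
    wm = _box((0.62, 0.5, 0.72), half) & ~csf
    for region, tag in ((csf, "CSF"), (wm, "WM")):
        core = ndimage.binary_erosion(
            region, structure=np.ones((3, 3, 3), dtype=bool), iterations=2
        )
        if not core.any():
            raise CohortConfigError(
                f"grid {grid_shape} too small: {tag} region has no eroded core"
            )

    parcellation = np.zeros(grid_shape, dtype=np.int16)
    labels: dict[int, tuple[str, str]] = {}
    for label, (name, side, frac, radius_mm) in DEFAULT_PARCELS.items():
        c = np.array(frac) * (np.array(grid_shape) - 1)
        r_vox = radius_mm / voxel_size
        sphere = (
            (idx[0] - c[0]) ** 2 + (idx[1] - c[1]) ** 2 + (idx[2] - c[2]) ** 2
        ) <= r_vox**2
        sphere &= brain & (parcellation == 0) & ~csf & ~wm
        if sphere.any():
            parcellation[sphere] = label
            labels[label] = (name, side)

    pv_csf = csf.astype(float)
    pv_wm = wm.astype(float)
    pv_gm = np.where(brain & ~csf & ~wm, 1.0, 0.0)
    pv_maps = {"wm": pv_wm, "csf": pv_csf, "gm": pv_gm}
    return brain, parcellation, pv_maps, labels


def _smooth_standardize_noise(
    rng: np.random.Generator,
    shape: tuple[int, int, int],
    n_t: int,
    sigma_vox: float,
    mask: np.ndarray,
) -> np.ndarray:
    """White noise per frame, Gaussian-smoothed and unit-variance in mask."""
    noise = rng.standard_normal(shape + (n_t,))
    if sigma_vox > 0:
        noise = ndimage.gaussian_filter(noise, sigma=(sigma_vox,) * 3 + (0.0,))
    flat = noise[mask]
    flat -= flat.mean(axis=0)
    flat /= flat.std(axis=0)
    noise[mask] = flat
    noise[~mask] = 0.0
    return noise


def _ar1_filter(noise: np.ndarray, phi: float) -> np.ndarray:
    """Turn temporally white frames into an AR(1) process with unit marginal
    variance: x_t = phi*x_{t-1} + sqrt(1-phi^2)*e_t."""
    if phi == 0:
        return noise
    out = np.empty_like(noise)
    out[..., 0] = noise[..., 0]
    innov_scale = np.sqrt(1.0 - phi**2)
    for t in range(1, noise.shape[-1]):
        out[..., t] = phi * out[..., t - 1] + innov_scale * noise[..., t]
    return out


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a cohort with the configured effect structure.

    Per subject, each run is ``BASELINE * (1 + sigma/100 * m(v) * x(v, t))``
    where ``x`` is spatially smoothed, temporally AR(1), unit-variance noise
    and ``m`` a per-voxel SD multiplier.  Inside each variability-effect
    parcel, ``m`` follows ``1 + EFFECT_AMPLITUDE*(r*z + sqrt(1-r^2)*eta)``
    with ``z`` the subject's standardized score and ``eta`` independent
    jitter, so the across-subject SD-vs-score correlation targets ``r``.
    For a connectivity effect, one latent AR(1) course per subject is added
    to the seed parcel at fixed amplitude and to the target parcel at an
    amplitude increasing linearly in the score.
    """
    cfg = config
    brain, parcellation, pv_maps, labels = build_anatomy(cfg.grid_shape, cfg.voxel_size)
    for label, _ in cfg.effect_rois:
        if label not in labels:
            raise CohortConfigError(f"effect ROI label {label} absent from parcellation")
    if cfg.connectivity_effect is not None:
        for label in cfg.connectivity_effect[:2]:
            if label not in labels:
                raise CohortConfigError(
                    f"connectivity label {label} absent from parcellation"
                )

    root = np.random.SeedSequence(cfg.seed)
    ss_scores, ss_effects, ss_subjects = root.spawn(3)
    rng_scores = np.random.default_rng(ss_scores)
    rng_effects = np.random.default_rng(ss_effects)

    scores = rng_scores.uniform(*cfg.score_range, size=cfg.n_subjects)
    fd_targets = rng_scores.uniform(*cfg.mean_fd_range, size=cfg.n_subjects)
    z = (scores - scores.mean()) / scores.std() if cfg.n_subjects > 1 else np.zeros(1)

    # per-subject SD multipliers for each variability-effect parcel
    multipliers: dict[int, np.ndarray] = {}
    for label, r_target in cfg.effect_rois:
        eta = rng_effects.standard_normal(cfg.n_subjects)
        latent = r_target * z + np.sqrt(1.0 - r_target**2) * eta
        multipliers[label] = np.clip(1.0 + EFFECT_AMPLITUDE * latent, 0.1, None)

    # per-subject target-parcel coupling amplitude (linear in score)
    if cfg.connectivity_effect is not None:
        seed_label, target_label, slope = cfg.connectivity_effect
        mid = 0.5 * (cfg.score_range[0] + cfg.score_range[1])
        target_amp = np.clip(0.25 + slope * (scores - mid), 0.0, None)

    sigma_vox = cfg.spatial_fwhm / (cfg.voxel_size * FWHM_TO_SIGMA)
    # RAS world affine with the left hemisphere at high x index: x_world
    # decreases with i, so high-i parcels (the "L" ones) get negative RAS x,
    # i.e. positive x after the LPS flip used in reports
    center = (np.array(cfg.grid_shape) - 1) / 2.0
    affine = np.diag([-cfg.voxel_size, cfg.voxel_size, cfg.voxel_size, 1.0])
    affine[:3, 3] = np.array([center[0], -center[1], -center[2]]) * cfg.voxel_size

    subjects: list[SubjectRecord] = []
    subject_seeds = ss_subjects.spawn(cfg.n_subjects)
    for i in range(cfg.n_subjects):
        ss_runs = subject_seeds[i].spawn(cfg.n_runs + 1)
        mult_map = np.ones(cfg.grid_shape)
        for label, m in multipliers.items():
            mult_map[parcellation == label] = m[i]

        runs, motions = [], []
        for j in range(cfg.n_runs):
            ss_noise, ss_latent, ss_motion = ss_runs[j].spawn(3)
            rng = np.random.default_rng(ss_noise)
            x = _smooth_standardize_noise(
                rng, cfg.grid_shape, cfg.n_timepoints_per_run, sigma_vox, brain
            )
            x = _ar1_filter(x, cfg.ar1_coeff)
            if cfg.connectivity_effect is not None:
                rng_l = np.random.default_rng(ss_latent)
                u = _ar1_filter(
                    rng_l.standard_normal((1, 1, 1, cfg.n_timepoints_per_run)),
                    cfg.ar1_coeff,
                )[0, 0, 0]
                x[parcellation == seed_label] += SEED_COUPLING * u
                x[parcellation == target_label] += target_amp[i] * u
            run = BASELINE * (1.0 + BASE_SIGMA_PCT / 100.0 * mult_map[..., None] * x)
            run[~brain] = 0.0
            runs.append(run.astype(np.float32))
            motions.append(
                generate_motion(cfg.n_timepoints_per_run, fd_targets[i], ss_motion)
            )

        subjects.append(
            SubjectRecord(
                subject_id=f"sub-{i + 1:02d}",
                runs=runs,
                motion=motions,
                brain_mask=brain.copy(),
                pv_maps={k: v.copy() for k, v in pv_maps.items()},
                score=float(scores[i]),
                affine=affine.copy(),
                tr=cfg.tr,
                rotation_unit="degrees",
            )
        )

    return Cohort(
        subjects=subjects,
        parcellation=parcellation,
        labels=labels,
        affine=affine,
        config=cfg,
    )


def save_cohort(cohort: Cohort, outdir: str | Path) -> Path:
    """Write a cohort to disk: NIfTI volumes, 6-column motion text files,
    a scores/manifest TSV, a parcel label table and a YAML config echo.
    Returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    affine = cohort.affine

    def _save(arr: np.ndarray, path: Path, dtype=np.float32, tr: float = 0.0) -> str:
        img = nib.Nifti1Image(np.asarray(arr, dtype=dtype), affine)
        if tr > 0:
            zooms = img.header.get_zooms()
            img.header.set_zooms(zooms[:3] + (tr,))
        nib.save(img, path)
        return str(path)

    _save(cohort.parcellation, outdir / "parcellation.nii.gz", np.int16)
    pd.DataFrame(
        [(k, n, s) for k, (n, s) in cohort.labels.items()],
        columns=["label", "name", "side"],
    ).to_csv(outdir / "labels.tsv", sep="\t", index=False)

    rows = []
    for sub in cohort.subjects:
        sdir = outdir / sub.subject_id
        sdir.mkdir(exist_ok=True)
        run_paths, motion_paths = [], []
        for j, (run, mot) in enumerate(zip(sub.runs, sub.motion)):
            run_paths.append(_save(run, sdir / f"run-{j + 1}.nii.gz", tr=sub.tr))
            mp = sdir / f"run-{j + 1}_motion.txt"
            np.savetxt(mp, mot, fmt="%.8f")
            motion_paths.append(str(mp))
        rows.append(
            {
                "subject_id": sub.subject_id,
                "score": sub.score,
                "runs": ";".join(run_paths),
                "motion": ";".join(motion_paths),
                "mask": _save(sub.brain_mask, sdir / "brain_mask.nii.gz", np.uint8),
                "wm_pv": _save(sub.pv_maps["wm"], sdir / "wm_pv.nii.gz"),
                "csf_pv": _save(sub.pv_maps["csf"], sdir / "csf_pv.nii.gz"),
                "gm_pv": _save(sub.pv_maps["gm"], sdir / "gm_pv.nii.gz"),
            }
        )
    manifest = outdir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)

    cfg = cohort.config
    cfg_dict = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in vars(cfg).items()
        if not k.startswith("_")
    }
    cfg_dict["effect_rois"] = [list(e) for e in cfg.effect_rois]
    if cfg.connectivity_effect is not None:
        cfg_dict["connectivity_effect"] = list(cfg.connectivity_effect)
    with open(outdir / "cohort_config.yaml", "w") as fh:
        yaml.safe_dump(cfg_dict, fh, sort_keys=True)
    return manifest
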