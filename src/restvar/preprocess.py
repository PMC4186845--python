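"""Per-subject preprocessing of resting-state BOLD runs.

The default pipeline mirrors a conventional AFNI/FSL resting-state stream:
spatial smoothing (3 mm FWHM Gaussian), discarding initial non-steady-state
frames, 19-regressor nuisance regression with the temporal mean restored
afterwards, conversion to percent-change units, and concatenation of runs.
Head motion is summarized as framewise displacement (FD): the sum of absolute
frame-to-frame changes of the three translations plus the three rotations
converted to mm of arc on a 50 mm sphere.

No low-pass filter is applied by default; an optional zero-phase Butterworth
filter (order 4, 0.08 Hz cut-off) is available for sensitivity analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

# FWHM -> Gaussian sigma conversion factor, 2*sqrt(2*ln 2)
FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

#: |temporal mean| below which a voxel is excluded from percent-change maps
MEAN_EPS = 1e-6


class PreprocessError(ValueError):
    """Raised for invalid preprocessing inputs (bad shapes, empty results)."""


@dataclass
class NuisanceDesign:
    """Design matrix of the 19 nuisance regressors.

    Columns: mean, linear and quadratic trends (time mapped to [-1, 1]);
    six rigid-body motion parameters and their first derivatives; mean WM
    and CSF time courses and their first derivatives.  First derivatives are
    backward differences with the first element set to 0, so every column
    has the same length as the data.
    """

    matrix: np.ndarray
    column_labels: list[str] = field(default_factory=list)
    condition_number: float = np.nan
    near_collinear: bool = False

    @property
    def n_regressors(self) -> int:
        return self.matrix.shape[1]


@dataclass
class PercentChangeSeries:
    """Per-voxel percent-change BOLD series (X, Y, Z, T), mean-centered.

    ``data`` is zero outside ``mask``; inside the mask every voxel's temporal
    mean is 0 by construction (percent change subtracts the mean first).
    """

    data: np.ndarray
    mask: np.ndarray
    tr: float

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[-1]


@dataclass
class FdTrace:
    """Framewise displacement series in mm; ``fd[0] = 0`` by convention.

    ``mean_fd`` averages frames 1..T-1 (the actual displacements).
    """

    fd: np.ndarray
    mean_fd: float
    head_radius: float


def discard_initial(series: np.ndarray, n_discard: int) -> np.ndarray:
    """Drop the first ``n_discard`` frames of a 4D series (time last axis).

    Motion traces must be trimmed identically by the caller.
    """
    n_t = series.shape[-1]
    if not 0 <= n_discard < n_t:
        raise PreprocessError(
            f"n_discard={n_discard} must satisfy 0 <= n_discard < T={n_t}"
        )
    return series[..., n_discard:]


def erode_mask_2d(mask: np.ndarray, width: int) -> np.ndarray:
    """Erode a 3D binary mask slice-by-slice (axial planes, last axis).

    Each z-slice is eroded independently ``width`` times with a 3x3 square
    structuring element, trimming ``width`` voxels off every in-plane border.
    """
    if width < 0:
        raise PreprocessError("erosion width must be >= 0")
    mask = np.asarray(mask, dtype=bool)
    if width == 0:
        return mask.copy()
    out = np.empty_like(mask)
    structure = np.ones((3, 3), dtype=bool)
    for k in range(mask.shape[2]):
        out[:, :, k] = ndimage.binary_erosion(
            mask[:, :, k], structure=structure, iterations=width
        )
    return out


def smooth_gaussian(series: np.ndarray, fwhm: float, voxel_size: float) -> np.ndarray:
    """Smooth each frame with an isotropic Gaussian of the given FWHM (mm)."""
    if fwhm < 0:
        raise PreprocessError("fwhm must be >= 0")
    if fwhm == 0:
        return np.asarray(series, dtype=float).copy()
    sigma_vox = fwhm / (voxel_size * FWHM_TO_SIGMA)
    series = np.asarray(series, dtype=float)
    if series.ndim == 3:
        return ndimage.gaussian_filter(series, sigma=sigma_vox)
    if series.ndim != 4:
        raise PreprocessError("expected a 3D frame or 4D series")
    # sigma 0 on the time axis: frames are smoothed independently
    return ndimage.gaussian_filter(series, sigma=(sigma_vox,) * 3 + (0.0,))


def tissue_region(
    pv_map: np.ndarray, threshold: float = 0.99, erode: int = 2
) -> tuple[np.ndarray, bool]:
    """Binary tissue region: partial-volume threshold then 3D erosion.

    Thresholding keeps voxels with ``pv >= threshold``; erosion (a 3x3x3 box
    applied ``erode`` times, i.e. shrinking the region in every direction)
    minimizes partial-voluming with neighbouring tissue.  Returns the region
    and an ``is_empty`` flag; an empty region is the caller's decision to
    handle (warned, not raised).
    """
    if not 0 < threshold <= 1:
        raise PreprocessError("threshold must be in (0, 1]")
    region = np.asarray(pv_map, dtype=float) >= threshold
    if erode > 0 and region.any():
        region = ndimage.binary_erosion(
            region, structure=np.ones((3, 3, 3), dtype=bool), iterations=erode
        )
    is_empty = not region.any()
    if is_empty:
        warnings.warn("tissue region is empty after threshold/erosion", stacklevel=2)
    return region, is_empty


def _backward_diff(x: np.ndarray) -> np.ndarray:
    """Backward difference along axis 0 with first element 0."""
    return np.diff(x, axis=0, prepend=x[:1])


def build_nuisance_design(
    motion: np.ndarray, wm_ts: np.ndarray, csf_ts: np.ndarray
) -> NuisanceDesign:
    """Assemble the 19-column nuisance design for one run.

    Trends use time rescaled to [-1, 1] (recorded in the column labels) for
    numerical conditioning; derivative columns are backward differences of
    their parent columns.  A condition number above 1e8 (or rank below 19)
    flags near-collinearity, e.g. identical WM and CSF time courses.
    """
    motion = np.asarray(motion, dtype=float)
    wm_ts = np.asarray(wm_ts, dtype=float).ravel()
    csf_ts = np.asarray(csf_ts, dtype=float).ravel()
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise PreprocessError("motion must be T x 6")
    n_t = motion.shape[0]
    if wm_ts.shape[0] != n_t or csf_ts.shape[0] != n_t:
        raise PreprocessError("motion, wm_ts and csf_ts lengths differ")
    if n_t < 20:
        raise PreprocessError(f"T={n_t} < 20: design would be rank-deficiency prone")

    t = np.linspace(-1.0, 1.0, n_t)
    cols = [np.ones(n_t), t, t**2]
    labels = ["mean", "linear[-1,1]", "quadratic[-1,1]"]
    for j in range(6):
        cols.append(motion[:, j])
        labels.append(f"motion{j}")
    dmotion = _backward_diff(motion)
    for j in range(6):
        cols.append(dmotion[:, j])
        labels.append(f"dmotion{j}")
    cols += [wm_ts, csf_ts, _backward_diff(wm_ts), _backward_diff(csf_ts)]
    labels += ["wm", "csf", "dwm", "dcsf"]

    matrix = np.column_stack(cols)
    # scale-invariant conditioning check on unit-normed columns
    norms = np.linalg.norm(matrix, axis=0)
    scaled = matrix / np.where(norms > 0, norms, 1.0)
    cond = float(np.linalg.cond(scaled))
    near_collinear = (
        cond > 1e8 or np.linalg.matrix_rank(matrix) < matrix.shape[1]
    )
    return NuisanceDesign(
        matrix=matrix,
        column_labels=labels,
        condition_number=cond,
        near_collinear=near_collinear,
    )


def regress_and_restore_mean(ts: np.ndarray, design: NuisanceDesign) -> np.ndarray:
    """OLS-remove the nuisance design from ``ts``, then add the mean back.

    ``ts`` is a length-T vector or a T x V matrix (one column per voxel).
    The fit uses the pseudo-inverse, so rank-deficient designs degrade
    gracefully to the minimum-norm solution.
    """
    ts = np.asarray(ts, dtype=float)
    vec_in = ts.ndim == 1
    y = ts[:, None] if vec_in else ts
    x = design.matrix
    if y.shape[0] != x.shape[0]:
        raise PreprocessError("time series length does not match design")
    beta = np.linalg.pinv(x) @ y
    resid = y - x @ beta
    out = resid + y.mean(axis=0, keepdims=True)
    return out[:, 0] if vec_in else out


def percent_change(ts: np.ndarray, mean_eps: float = MEAN_EPS) -> np.ndarray:
    """Convert a raw series to percent change: 100*(ts - mean)/mean.

    Raises on a near-zero temporal mean; batch callers instead drop such
    voxels from the analysis mask (see :func:`preprocess_run`).
    """
    ts = np.asarray(ts, dtype=float)
    mean = ts.mean(axis=0)
    if np.any(np.abs(mean) <= mean_eps):
        raise PreprocessError(
            f"temporal mean within {mean_eps} of zero: percent change undefined"
        )
    return 100.0 * (ts - mean) / mean


def concatenate_runs(runs: list[PercentChangeSeries]) -> PercentChangeSeries:
    """Concatenate percent-change runs along time.

    Percent change is computed per run before concatenation, so each run
    contributes a mean-zero segment.  Masks may differ slightly per run
    (near-zero-mean exclusions); the intersection is used.
    """
    if not runs:
        raise PreprocessError("no runs to concatenate")
    grid = runs[0].data.shape[:3]
    tr = runs[0].tr
    for r in runs[1:]:
        if r.data.shape[:3] != grid:
            raise PreprocessError("runs are on different grids")
        if r.tr != tr:
            raise PreprocessError("runs have different TR")
    mask = np.logical_and.reduce([r.mask for r in runs])
    data = np.concatenate([r.data for r in runs], axis=-1)
    data[~mask] = 0.0
    return PercentChangeSeries(data=data, mask=mask, tr=tr)


def framewise_displacement(
    motion: np.ndarray,
    head_radius: float = 50.0,
    rotation_unit: str = "degrees",
) -> FdTrace:
    """Framewise displacement from a T x 6 motion trace.

    fd[t] = sum |delta translation_i| + sum head_radius * |delta rotation_j|,
    rotations converted to radians first.  Columns 0-2 are translations (mm),
    3-5 rotations.  fd[0] = 0; mean_fd averages frames 1..T-1.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise PreprocessError("motion must be T x 6")
    if motion.shape[0] < 2:
        raise PreprocessError("need at least 2 frames for FD")
    if rotation_unit == "degrees":
        rot_scale = np.pi / 180.0
    elif rotation_unit == "radians":
        rot_scale = 1.0
    else:
        raise PreprocessError(f"unknown rotation unit: {rotation_unit!r}")
    delta = np.diff(motion, axis=0)
    fd_body = np.abs(delta[:, :3]).sum(axis=1) + head_radius * rot_scale * np.abs(
        delta[:, 3:]
    ).sum(axis=1)
    fd = np.concatenate([[0.0], fd_body])
    return FdTrace(fd=fd, mean_fd=float(fd_body.mean()), head_radius=head_radius)


def lowpass_filter(data: np.ndarray, tr: float, cutoff_hz: float = 0.08) -> np.ndarray:
    """Optional zero-phase low-pass (Butterworth order 4) along the last axis.

    Off by default in the pipeline; high-frequency BOLD content is retained.
    """
    nyq = 0.5 / tr
    b, a = signal.butter(4, cutoff_hz / nyq, btype="low")
    return signal.filtfilt(b, a, data, axis=-1)


def preprocess_run(
    run: np.ndarray,
    motion: np.ndarray,
    brain_mask: np.ndarray,
    wm_region: np.ndarray,
    csf_region: np.ndarray,
    tr: float,
    voxel_size: float,
    n_discard: int = 5,
    fwhm: float = 3.0,
    lowpass: bool = False,
) -> PercentChangeSeries:
    """Run the default per-run pipeline: smooth, discard, regress, percent change.

    The WM/CSF nuisance time courses are the mean signals over the supplied
    (already thresholded and eroded) tissue regions, computed from the
    smoothed post-discard data.  Voxels whose temporal mean is within
    ``MEAN_EPS`` of zero are dropped from the output mask.
    """
    brain_mask = np.asarray(brain_mask, dtype=bool)
    smoothed = smooth_gaussian(np.asarray(run, dtype=float), fwhm, voxel_size)
    data = discard_initial(smoothed, n_discard)
    motion_trim = np.asarray(motion, dtype=float)[n_discard:]

    wm_ts = data[np.asarray(wm_region, dtype=bool)].mean(axis=0)
    csf_ts = data[np.asarray(csf_region, dtype=bool)].mean(axis=0)
    design = build_nuisance_design(motion_trim, wm_ts, csf_ts)

    vox = data[brain_mask]  # V x T
    cleaned = regress_and_restore_mean(vox.T, design).T  # V x T

    mean = cleaned.mean(axis=1)
    valid = np.abs(mean) > MEAN_EPS
    pc_vox = np.zeros_like(cleaned)
    pc_vox[valid] = 100.0 * (cleaned[valid] - mean[valid, None]) / mean[valid, None]

    out_mask = np.zeros_like(brain_mask)
    out_mask[brain_mask] = valid
    out = np.zeros(data.shape, dtype=float)
    out[brain_mask] = pc_vox
    out[~out_mask] = 0.0
    if lowpass:
        out[out_mask] = lowpass_filter(out[out_mask], tr)
        out[out_mask] -= out[out_mask].mean(axis=-1, keepdims=True)
    return PercentChangeSeries(data=out, mask=out_mask, tr=tr)
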