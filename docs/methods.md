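# Methods

## The analysis model

The pipeline treats each subject's resting-state BOLD data as a 4D image
series on a common grid with a brain mask, tissue partial-volume maps, an
integer parcellation, a 6-parameter rigid-body motion trace per run, and
one scalar behavioral score per subject. The question asked is purely
across-subject: at which voxels does an fMRI summary statistic (temporal SD
of the percent-change signal, or Fisher-z seed correlation) correlate with
the behavioral score over the cohort?

With n subjects the across-subject statistic is the Pearson correlation r
with two-tailed p from t = r√((n−2)/(1−r²)) on n−2 df. This is exactly the
slope t-test of a simple linear regression, which is how such analyses are
usually phrased; the correlation form makes the effect size directly
readable. At n = 10 the two-tailed 5% point is |r| ≈ 0.63, which sets the
scale for what such small cohorts can detect: only strong brain-behavior
couplings (r on the order of 0.7–0.95) survive voxelwise thresholding plus
cluster correction.

### Preprocessing order and conventions

Per run: Gaussian smoothing (3 mm FWHM; σ_vox = FWHM/(2√(2 ln 2)·voxel)),
discard of the first 5 frames, nuisance OLS with the mean restored,
percent-change conversion, then concatenation of runs. Choices the
literature leaves open, fixed here and carried in metadata:

* **First derivatives** are backward differences with the first element 0,
  keeping regressor lengths equal to the data.
* **Trend columns** use time rescaled to [−1, 1] for conditioning; the
  convention is recorded in the column labels.
* **Mean restoration**: the temporal mean is added back after nuisance
  regression so percent change is taken against a meaningful baseline.
* **Near-zero-mean voxels** (|mean| ≤ 1e-6 raw units) are removed from the
  analysis mask instead of producing unstable ratios.
* **SD** uses the population formula (ddof = 0) by default; with ~100–470
  frames the sample/population difference is far below the across-subject
  variation of interest. The choice is stored on every `VariabilityMap`.
* **FD** follows the translation-plus-rotation-arc form with a 50 mm head
  radius; rotations default to degrees (the convention the motion files
  use, declared on the record), fd[0] = 0, and mean FD averages frames
  1..T−1.
* **Low-pass filtering** is off by default (high-frequency BOLD content is
  retained); a zero-phase Butterworth (order 4, 0.08 Hz) is available for
  sensitivity analyses and strictly reduces voxel SD.
* **Brain mask** is eroded 2 voxels per axial slice; WM/CSF nuisance
  regions use partial volume ≥ 0.99 followed by 2 iterations of 3×3×3
  erosion, minimizing gray-matter contamination.

### Cluster-extent correction

The correction is a Monte-Carlo simulation in the AlphaSim family: fill
the analysis mask with white Gaussian noise, smooth at the preprocessing
FWHM, restandardize within the mask, apply the two-tailed voxelwise
threshold, and record the largest suprathreshold connected component;
k_min is the smallest extent whose null exceedance probability is ≤ α
(read directly off the empirical tail: with sizes sorted ascending and
m = ⌈n(1−α)⌉, k_min is one more than the m-th smallest maximum). Defaults:
voxel p = 0.05 two-tailed, α = 0.05, 1000 iterations, faces-touch
(6-neighbor) connectivity; edges/corners are selectable. Clusters in the
real map are split by the sign of r before labeling, so positive and
negative effects are reported separately; the null simulation thresholds
|z| without sign-splitting, which makes the null components no smaller
than sign-split ones and the correction correspondingly conservative.

The null smoothness is the *applied* smoothing FWHM, not an estimate of
residual smoothness; the synthetic generator imposes its spatial
correlation by the same smooth-then-restandardize construction, so
generator and null simulator agree by design. On real data with intrinsic
smoothness beyond the applied kernel this choice would be anticonservative;
a residual-smoothness estimator is deliberately out of scope.

Reports give, per cluster: the parcellation label at the peak (max |r|,
ties broken by smallest linear index), the hemisphere from the sign of the
left-right world coordinate, extent, peak coordinates mapped through the
NIfTI affine and flipped to the requested orientation (LPS by default,
where left-hemisphere x prints positive), and peak r and p. Per-parcel
voxel counts of each cluster are attached for multi-parcel clusters.

## The synthetic cohort generator

`generate_cohort` draws, per subject and run,

    y(v, t) = B · (1 + σ/100 · m(v) · x(v, t)),    B = 1000, σ = 1 %

where x is unit-variance noise built by Gaussian-smoothing white frames at
the configured FWHM (3 mm default), restandardizing within the brain mask,
and AR(1)-filtering over time (coefficient 0.4 by default — a simple model
with realistic temporal autocorrelation). Scores are uniform on [76, 96] %
and mean-FD targets uniform on [0.06, 0.11] mm, the ranges typical of a
small, low-motion adult cohort performing this kind of task; motion traces
are Gaussian random walks rescaled so the Power-formula mean FD hits the
target exactly. Study-scale defaults are 10 subjects, two 240-frame runs
at TR 2 s on a 48×56×40 grid of 2 mm voxels.

**Variability effects.** Inside a chosen parcel the SD multiplier is
m_i = 1 + 0.25·(r·z_i + √(1−r²)·η_i), with z_i the subject's standardized
score and η_i independent N(0,1) jitter. The construction makes the
across-subject correlation of the (ROI-mean) SD with the score converge to
the target r as the jitter vanishes and measurement noise shrinks; the
amplitude 0.25 keeps multipliers positive over realistic draws. Effects
are ROI-homogeneous — real effects surely vary within a region, but no
within-region profile is available to emulate, and homogeneity is the
conservative default for testing cluster recovery.

**Connectivity effects.** One latent AR(1) course per subject and run is
added to the seed parcel at fixed amplitude 0.3 and to the target parcel
at amplitude clipped(0.25 + slope·(score_i − midrange)). The analyses use
slope = 0.03 per score percent, chosen so the injected z-vs-score effect
across subjects lands in the same strong-effect band (median voxel r ≈
0.6–0.8) as the variability target of 0.9 — the regime the design is meant
to detect.

**Anatomy.** The brain is an ellipsoid; parcels are spheres at fixed
fractional positions with left/right labels (left hemisphere at high grid
index; the stored RAS affine flips x so LPS reports print left as
positive x); WM and CSF are rectangular deep-tissue blocks thick enough to
survive the 0.99/2-voxel-erosion nuisance-region definition. Everything is
deterministic given the config seed, with per-subject and per-run streams
spawned from one root `SeedSequence`.

**What the generator does not emulate** — and therefore what passing tests
do not establish about real data: physiological (cardiac/respiratory)
noise, motion-induced image artifacts (motion traces are generated but do
not corrupt the images), intrinsic smoothness beyond the applied kernel,
non-Gaussian BOLD amplitude distributions, multi-echo signal properties,
registration error, and any true neural coupling structure beyond the
injected effects. The tests establish that the *pipeline* is correct and
calibrated under its own assumptions, not that those assumptions hold in
vivo.

## Problem sizes

Simulation studies (tests, analysis drivers, the acceptance script) run on
a 20×20×16 grid of 2 mm voxels with one 100-frame run per subject and
n = 10 — large enough that masks contain thousands of voxels, parcels tens
of voxels, and the nuisance design is well-conditioned, while a full
20-replicate recovery study completes in well under a minute. The
familywise-error calibration uses a 40×40×40 all-true mask with 1000
calibration and 1000 fresh null iterations. The generator's study-scale
defaults (48×56×40, two 240-frame runs) remain the package defaults and
are exercised directly by the anatomy tests.

## Known limitations

* The empirical k_min is a step function of α with resolution 1/n_iter; a
  warning fires when α is below that resolution.
* Percent-change conversion assumes a positive stable baseline; voxels
  near zero mean are dropped rather than imputed.
* Pearson-based inference assumes approximate bivariate normality across
  subjects; at n = 10 outliers can dominate, which is inherent to the
  design being modeled, not to the implementation.
* The seed-interior voxels are retained in connectivity maps (they
  correlate with the seed by construction); cluster reports can be read
  against the parcel-count breakdown to discount them.
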