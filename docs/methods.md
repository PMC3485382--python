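# Methods

## Scope and data model

`lfoamp` implements the voxelwise low-frequency-oscillation amplitude
analysis of a two-group resting-state fMRI study on data that are already
aligned to a common grid: temporal preprocessing, ALFF/fALFF computation,
gray-matter masking and standardization, group statistics with covariates,
clinical-score correlations, and Monte Carlo cluster-extent correction.
Slice-timing correction, realignment, spatial normalization and tissue
segmentation are deliberately out of scope: the synthetic cohorts are
generated directly on the common grid, and motion enters only as the
per-axis summary maxima used for screening.

Volumes are NIfTI-1; voxel indices are 0-based and map to voxel centers in
mm through the affine. Cohort manifests are tab-separated UTF-8 tables with
a header row and `.` for missing values.

## Preprocessing

- **Volume dropping.** The first 10 volumes of each run are discarded
  (scanner equilibration / subject adaptation), leaving 200 analyzed
  volumes of the default 210 acquired. The 210-volume default is a
  convention of the generator; only the 200 analyzed volumes matter
  downstream.
- **Motion screening.** A subject passes if every translation maximum is
  strictly below 1 mm and every rotation maximum strictly below 1 degree
  (the comparison is strict because the criterion is "less than"). The
  screen is monotone: worsening any entry can never rescue a subject.
- **Spatial smoothing.** Separable Gaussian, sigma = FWHM/sqrt(8 ln 2) per
  axis converted to voxels, reflective boundaries (which conserve the
  global mean). Default FWHM 4 mm.
- **Detrending.** Per-voxel least-squares line (intercept + slope) removed
  via an orthonormal basis, so residuals are exactly orthogonal to the
  design.
- **Band-pass.** An ideal DFT-bin mask: bins with f_lo <= f <= f_hi
  (inclusive edges, 1e-9 Hz tolerance against floating-point bin
  frequencies) are kept, all others zeroed. An ideal mask rather than an
  IIR filter makes filtering *exactly* consistent with the in-band
  amplitude average used by ALFF — both select the same bins — and is
  idempotent. Band edges at 0.01 and 0.08 Hz are treated as inclusive; the
  choice is configurable and irrelevant for bin-aligned content.
- **Group GM mask.** Voxels where the cohort-mean GM probability exceeds
  0.15. The comparison is strict `>` (configurable); at the default
  threshold the distinction only matters for ties.

## Amplitude metrics

The one-sided amplitude convention is `A_0 = |X_0|/N` and `A_k = 2|X_k|/N`
for every k > 0 (including the Nyquist bin), so a unit sinusoid at a bin
frequency has amplitude exactly 1. ALFF is the *mean* in-band amplitude
(sum and mean differ by a constant that cancels after standardization).
fALFF is the in-band amplitude sum divided by the sum over the full band
(0, Nyquist]; the DC bin is excluded from the denominator because it
measures the series mean, not a fluctuation (`include_dc` restores the
literal 0-based band). Zero-variance voxels get ALFF = fALFF = 0.
Standardization divides each subject's map by its own in-mask mean and
zeroes out-of-mask voxels, making the absolute amplitude scale (and hence
the amplitude convention) irrelevant to group inference.

For white noise the expected fALFF is the in-band / full-band bin-count
ratio (29/100 for N = 200, TR = 2 s); uniform doubling of all non-DC bins
keeps the Nyquist bin's expected amplitude commensurate with interior bins
so this ratio holds without a half-bin correction.

## Group statistics

Two-sample maps use the pooled-variance t (patients minus controls,
df = n_a + n_b − 2), the standard neuroimaging choice; Welch is available
behind a flag. The covariate GLM regresses amplitude on [intercept, group
indicator, scalar covariates, voxelwise covariates] per voxel; scalar
covariates are mean-centered and voxelwise covariates centered per voxel so
the group coefficient remains the adjusted group difference. With no
covariates the GLM reproduces the pooled t exactly (algebraic identity,
tested to 1e-10). Rank-deficient voxels (eigenvalue ratio < 1e-10) are
excluded from the analyzed mask and counted; zero-variance voxels get t = 0
with a count. Correlation maps are Pearson r (partial r after residualizing
both sides on the covariates), df = n − 2 − #covariates, with
t = r sqrt(df/(1 − r²)) for thresholding. All inference is two-sided, with
positive and negative effects handled as separate cluster families.

## Monte Carlo cluster-extent correction

Per iteration: standard Gaussian noise on the mask's grid, Gaussian
smoothing at the *applied* FWHM (4 mm default; residual-based smoothness
estimation is out of scope), renormalization to zero mean / unit variance
over in-mask voxels, thresholding, and the maximum cluster size across both
signs. The minimum extent k_min is the smallest size whose exceedance
fraction is at most the familywise alpha; `k_min_mm3` is k_min times the
voxel volume.

Two conventions follow the AFNI/REST AlphaSim program rather than a
two-sided reading:

- `voxel_p` is the **one-tailed** per-voxel suprathreshold probability:
  the Gaussian threshold is `Phi^-1(1 − p)` (1.645 at p = 0.05), and stat
  maps are thresholded at the matching `t_df^-1(1 − p)`, keeping the
  familywise calibration internally consistent.
- Cluster connectivity defaults to the **18-neighborhood** (faces +
  edges): AlphaSim's default cluster-connection radius of 5 mm connects
  exactly the 18-neighborhood at 3 mm voxels. On a whole-brain MNI152 GM
  mask (probability > 0.15 at 3 mm, 65,700 voxels) these defaults give a
  minimum cluster volume of ≈1,620–1,650 mm³ (60–61 voxels), consistent
  with the ~1,566 mm³ scale reported for this parameter set in the
  literature the package emulates; the 26-neighborhood would inflate this
  to ≈2,200 mm³. Both alternatives remain configurable.

The null is Gaussian while the stat maps are t with modest df — the same
approximation the original program makes; the voxel-level threshold is
exact per map via its df, only the cluster-extent distribution inherits
the Gaussian shape.

## Synthetic cohort generator

The generator emulates the study conditions: 18 subjects per group
(configurable), 64×64×30 grid of 3 mm voxels (tests use 24×24×16 for
speed), TR = 2 s, 210 acquired volumes, an ellipsoidal brain mask filling
~80% of the half field of view, and demographics matched across groups
(paired ages with 2-year jitter, identical sex sequences giving a 9/9
split at n = 18, HRSD ~ N(25, 5) for patients and N(4, 3) truncated to
[0, 6] for controls, HAMA ~ N(17, 6), illness duration ~ N(5, 4) months,
motion drawn below the screening thresholds).

Per voxel the BOLD signal is baseline (100) + linear drift + in-band
sinusoids + aliased physiological sinusoids (0.11 and 0.2 Hz) + 1/f^β
background noise (β = 1, time-domain SD 1.0, generated in the frequency
domain with random phases). The in-band components (0.02–0.065 Hz,
amplitudes 1.2 down to 0.7, all bin-aligned at N = 200) are scaled by a
global per-subject lognormal factor (CV 0.10), a voxelwise lognormal
jitter field (CV 0.12) and, for patients inside a planted sphere, the
effect's amplitude ratio.

Two modeling choices matter for calibration and are deliberate:

- **Effects are multiplicative on oscillation amplitude**, not additive on
  the signal, because ALFF/fALFF are amplitude metrics — ground truth must
  be stated in amplitude units.
- **Oscillation phase is shared across voxels within a subject** (per
  component), modeling regionally coherent low-frequency oscillations.
  Spatial smoothing then combines amplitudes linearly, so amplitude maps
  inherit exactly the applied 4 mm smoothness — the assumption the
  Monte Carlo correction makes. With voxel-independent phases the
  magnitude transform would roughly square the spatial correlation,
  leaving stat maps rougher than the null assumes and the correction
  overly conservative.

GM maps are a constant mean level (0.55) plus a smooth (6 mm FWHM)
Gaussian field (SD 0.08) inside the brain mask, clipped to [0, 1], with
`gm_volume` effects applied multiplicatively for patients.

What the generator does **not** model: hemodynamic response shapes, motion
corruption of images, intrinsic spatial noise correlation, non-stationary
physiological noise, multi-site effects, and realistic anatomy (the brain
is an ellipsoid; the GM map has no tissue structure). Passing tests
therefore demonstrate correctness of the *computational chain* and its
calibration under the stated noise model, not robustness to real-data
artifacts.

## Numerical choices and degenerate inputs

- fALFF at zero-denominator voxels is 0; standardization refuses in-mask
  means below 1e-12; bands must contain at least one DFT bin.
- Detrending requires ≥3 time points; group tests require ≥2 subjects per
  group; correlations ≥3 subjects and non-constant scores (the pipeline
  skips — with a logged warning — correlation maps it cannot compute
  rather than failing the run).
- Cluster ordering is deterministic: by size descending, ties broken by
  the peak voxel's flat index, making outputs byte-reproducible.
- All randomness flows from explicit integer seeds; per-subject streams
  are keyed by (seed, CRC-32 of subject id, stream tag), so cohorts are
  reproducible subject-by-subject and byte-identical on regeneration
  (gzip members are written with a zero mtime).

## Calibration results, problem sizes and limitations

The test suite checks, at reduced problem sizes chosen to keep a full run
in minutes: null-cohort voxelwise rejection at nominal 5% and familywise
surviving-cluster rate within [0.02, 0.08] (50 replicate 10+10 cohorts on
the 24×24×16 grid, 500-iteration nulls); whole-brain k_min at 2,000
iterations; and recovery of a planted ratio-1.5, 9 mm sphere at 18+18
subjects for both metrics with and without covariates. The measured
familywise rate sits at the conservative edge of the band: the amplitude
maps' residual smoothness is slightly below the applied 4 mm (the
voxelwise jitter field is smoothed only by preprocessing, while the
background-noise contribution to amplitude variance decorrelates faster),
so the 4 mm Gaussian null mildly over-estimates cluster sizes — the same
direction of bias the fixed-FWHM AlphaSim convention has on real data
whose intrinsic smoothness is below the assumed value.

A global-mean side effect worth knowing: standardization divides by the
in-mask mean, so a planted amplitude *increase* slightly depresses all
other voxels of the patient maps. On the reduced test grid (where the
sphere is ~5% of the mask) this produces a broad, weak negative field
around a strong planted positive effect; at whole-brain mask sizes the
shift is negligible. This mirrors the behavior of mean-scaled ALFF
analyses on real data.
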