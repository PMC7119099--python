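# Methods

`handquant` quantifies hand muscle volume and intramuscular fat from paired
T1-weighted and 2-point Dixon MRI volumes, and reproduces the accompanying
cohort analysis. This note documents the models, the parameters that matter,
the synthetic data the package is validated on, and the design decisions
taken where the underlying method left choices open.

## Per-subject pipeline

The analysis chain for one scan is

1. **Bias-field correction.** MRI surface coils impose a smooth
   multiplicative intensity modulation ("bias field") on the image:
   `observed = true × field`. We remove it with N4 nonuniform intensity
   normalization (SimpleITK's `N4BiasFieldCorrectionImageFilter`):
   iterative log-domain B-spline field estimation driven by histogram
   sharpening, restricted to an Otsu foreground mask and estimated on a
   2× shrunken volume (the field is smooth, so nothing is lost).
   Defaults: 3 fitting levels, ≤50 iterations per level, convergence
   threshold 10⁻³. Fewer fitting levels mean a stiffer field; three levels
   were chosen so that an unbiased (but noisy, multi-tissue) image yields a
   near-unit estimated field while genuinely biased images are still
   corrected to a fraction of their original within-tissue coefficient of
   variation. Two post-processing steps are ours:
   - The B-spline extrapolation into air is not identified by any data, so
     outside the foreground the log field is replaced by a bounded smooth
     extension (normalized convolution) and decayed to zero with a Gaussian
     in the physical distance from tissue (scale `background_decay_mm`,
     default 10 mm).
   - The field is rescaled so the corrected volume preserves the global mean
     intensity exactly; correction changes spatial modulation, never the
     intensity scale.

2. **Hand cross-sectional area (CSA).** Per slice: threshold →
   morphological closing (disk radius 2 voxels) → hole filling (absorbing
   interior hypointense structures such as bone and tendon into the hand
   area) → removal of components smaller than `min_component_area_mm2`
   (default 30 mm²). The default threshold is Otsu on the **volume**
   histogram rather than per-slice: a slice containing no hand has a
   single-mode histogram, and per-slice Otsu would invent a foreground
   there. Per-slice Otsu and fixed thresholds remain available. Slices with
   no hand yield empty contours; only an entirely empty volume is an error.

3. **Random-forest muscle segmentation.** Every hand voxel is described by
   neighborhood features: raw intensity, Gaussian-smoothed intensity at 1
   and 2 mm, local mean and SD in cubic neighborhoods of radius 1 and 2
   voxels, gradient magnitude (physical spacing aware), distance to the
   hand boundary (mm), and normalized slice position. A random forest
   (default 100 trees, unlimited depth, balanced class weights, fixed seed)
   classifies muscle vs background; the union of muscle voxels is the
   muscle volume of interest (VOI). The classifier is trained on labeled
   scans — on synthetic phantoms the ground-truth muscle labels stand in
   for manual segmentations. Serialized models carry the feature-name
   fingerprint and refuse to predict under a mismatched feature
   configuration.

4. **Gaussian histogram cleanup.** A Gaussian is fitted to the intensity
   histogram of the muscle VOI (Freedman–Diaconis bins, nonlinear least
   squares seeded by median/MAD; robust median/MAD fallback if the fit
   fails) and voxels outside mean ± 2 fitted SDs are removed. This strips
   hypointense tendon/ligament and hyperintense vessel voxels wrongly
   included by the classifier. The *fitted* parameters, not the sample
   moments, define the window — the sample moments are corrupted by the
   very contaminants the step removes. The cut is applied once. Note a
   deliberate consequence: on a perfectly clean Gaussian VOI the ±2σ window
   retains ≈95.4% of voxels, so measured muscle volumes sit ≈4.6% below the
   label-count truth; this bias is shared by any reanalysis of the same
   scan and cancels in precision and group comparisons. A constant-intensity
   VOI (σ below tolerance) retains all voxels and flags the report.

5. **Volumetrics.** Between the user-defined proximal and distal MCP-III
   slice bounds (0-based, inclusive on both ends): hand volume `V_H` and
   muscle volume `V_M` are in-bounds voxel counts × voxel volume
   (dx·dy·dz mm³), and `V_M_rel = V_M / V_H`.

6. **Dixon fat quantification.** From the water/fat pair,
   `I_ff = round(fat / (water + fat) × 1000)`, an integer map where one
   grey value is 0.1% fat; voxels with zero total signal are set to 0 and
   flagged in a validity mask rather than NaN, keeping the map integer.
   The bias-corrected T1 (restricted to the hand mask) is registered onto
   the Dixon frame by rigid multimodal registration — Mattes mutual
   information (32 bins, 25% regular sampling with fixed seed),
   multi-resolution (2 levels), regular-step gradient descent, moments
   initialization — and the muscle VOI is resampled onto the Dixon grid
   with nearest-neighbour interpolation (masks stay binary; linear
   interpolation is deliberately rejected for masks). Then
   `V_F = Σ_muscle voxel_volume × I_ff/1000` and `V_F_rel = V_F / V_M`
   with `V_M` recomputed on the Dixon grid so numerator and denominator
   share a grid.

## Reanalysis precision

Repeated analyses of the same scans are summarized per parameter by the
densitometry convention: per dataset, the standard deviation (n−1
denominator — with 3 repeats the choice matters) and the coefficient of
variation SD/mean; across datasets, the root-mean-square average of each
(RMS-SD in the unit of the variable, RMS-CV in %). Datasets with zero mean
are excluded from RMS-CV and flagged. Manual operator editing is replaced
by a deterministic pipeline, so reanalysis variability is exercised by
`perturb_for_reanalysis`: seeded Gaussian intensity noise whose RMS scales
linearly with the magnitude parameter and vanishes at 0.

## Cohort statistics

Cross-sectional cohort of three diagnosis groups — psoriasis (Pso, the
control group), psoriatic arthritis (PsA) and rheumatoid arthritis (RA) —
always stratified by sex. Responses (`vh` in cm³, `vmrel`, fat measures)
are modeled by OLS on age (or age³, motivated by the grip-strength–age³
association), optionally BMI, and diagnosis as a categorical factor with
Pso as reference. Records lacking BMI are dropped only when BMI is in the
model (the "BMI-available subset" semantics), never silently — the fitted
model reports n.

- **Adjusted group difference Δ**: the model-predicted mean difference
  between two diagnoses averaged over the age window. The default model has
  parallel slopes (no age × diagnosis interaction), where Δ reduces exactly
  to the factor-coefficient difference and its p-value is the t-test of the
  linear contrast; with the optional interaction model, Δ is the
  window-averaged predicted difference with the averaged contrast vector.
  Parallel slopes is the default because a single age-averaged Δ per
  contrast is the reporting convention being reproduced.
- **Percent change over an age window** [a, b]:
  `100 × (pred(b) − pred(a)) / pred(a)`, anchored at the lower endpoint,
  other covariates at stratum means and diagnosis at observed group shares.
- **Decade analysis**: ages partitioned into the 5th–8th decades as
  [40,50), [50,60), [60,70), [70,80] — left-closed/right-open with the last
  decade closed, a convention that must be fixed and is tested. Per decade:
  one-way ANOVA across diagnoses plus Tukey HSD pairwise comparisons.
  Decades with fewer than two groups of ≥2 records are reported as not
  testable, not errors. Significance threshold 0.05; no correction beyond
  Tukey. (`include_pairwise=False` skips the studentized-range p-values,
  which dominate the cost of large null simulations.)

## Synthetic data

No patient images accompany the package, so every stage is validated on
generated data with known truth.

**Phantom.** A schematic hand — palm slab plus four finger cylinders along
the slice axis — containing muscle blobs (thenar/hypothenar-like plus an
interossei-like strip), metacarpal-like bone rods, thin hypointense tendon
rods and hyperintense vessel rods. Geometry scales with the grid; default
96×96×24 at 1.0×1.0×3.0 mm, a desk-scale downscaling of a clinical hand
protocol (320×320 in-plane at 0.5×0.5 mm, 64 T1 / 30 Dixon slices, 3.0 mm
thick); the Dixon grid covers the central 12 slices and is displaced by a
stored rigid transform (default 5° rotation, (2.5, 3.0, 1.0) mm
translation ≈ 4 mm magnitude). T1 = tissue mean × bias field + Gaussian
noise; the bias field is `exp` of a smooth normalized random field
(Gaussian-filtered noise, correlation length 40 mm, peak |log field| = the
amplitude parameter, default 0.2). No intensity statistics exist for the
real tissues, so the phantom means are free parameters chosen for a
fat-suppressed T1 contrast ordering (air 5, tendon 25, bone 30, other soft
tissue 55, muscle 100, vessel 220; noise SD 4). Dixon water/fat are built
from the label volume on the Dixon grid so `fat/(water+fat)` equals the
per-compartment fat fraction exactly before noise (muscle default 0.10,
marrow 0.5, subcutaneous/connective 0.6). Truth volumes are exact label
counts × voxel volume.

What the phantom does **not** emulate: anatomy, partial-volume mixing at
tissue boundaries, MR relaxometry, motion, water–fat swaps. Passing tests
therefore demonstrate the pipeline's correctness and calibration under
idealized contrast, not clinical segmentation accuracy.

**Cohort.** One row per subject from the six diagnosis × sex groups with
the study-structure sizes 63/38/61/76/41/51 and group age distributions
(truncated normal on [20, 80], e.g. RA males n=41 at 62±12 y). Outcomes
follow `y = intercept(sex) + offset(diagnosis) + slope(sex)·(age−40) +
noise`, with BMI present for 206/330 of subjects. Default effects are
chosen to be realistic for the modeled diseases (males ~14% higher
`vmrel`; RA offset −0.035; male slope −7×10⁻⁴/y, i.e. ~13% loss over
40–80 y for controls; residual SD 0.025). The generating coefficients are
returned with the table so recovery, CI coverage and type-I error can be
measured.

## Numerical choices and degenerate inputs

- Volumes are float32 on disk (NIfTI-1), masks uint8; the array axis order
  is (slice, row, col) with spacing (dx, dy, dz).
- Rigid transforms: ZYX Euler angles in degrees about an explicit center,
  translations in mm; composition/inversion via SimpleITK. Recovered and
  true transforms are compared by their *action* on probe points (different
  rotation centers make parameter-wise comparison meaningless); the
  accuracy criterion is half the coarsest voxel dimension (1.5 mm at 3 mm
  slices) and 1°.
- Gaussian-cleanup degenerate cases: <50 voxels is an error; σ below
  tolerance retains everything and flags the report.
- Fat-fraction division by zero → grey value 0 + validity flag.
- All stage seeds derive deterministically (SHA-256) from one global seed;
  reruns with equal config hash and seed are byte-identical.

## Problem sizes used in validation

The test suite and the acceptance script run entirely on the default
downscaled phantom geometry: 3 training + 10 evaluation phantoms for
volume recovery, 3 seeds for bias-correction checks, 2 phantoms with Dixon
pairs for registration, 5 phantoms × 3 perturbed repeats for the
reanalysis-precision experiment, 100 cohort replicates for CI coverage and
1000 null replicates (4000 decade ANOVAs) for type-I error calibration.

## Known limitations

- The feature set, tree count and training regime of the original
  classifier are unreported; ours are package defaults, config-exposed.
- Whether the ±2σ window uses fitted or sample moments was unspecified;
  fitted parameters are used (it is a *fit* of the histogram), and the
  systematic ≈4.6% volume understatement this implies is documented above.
- Registration operates on hand-masked volumes, not extracted surfaces.
- 2-point Dixon only: no T2*/B0 correction, no swap detection.
- The cohort model is linear(-in-age³ optionally) and cross-sectional;
  no longitudinal or mixed-effects structure.
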