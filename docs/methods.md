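# Methods

This note documents the models, defaults and numerical choices behind
`ramancell`, in the spirit of a statistical software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Data model

A `SpectraSet` is a cells × channels intensity matrix on one strictly
ascending wavenumber grid (cm⁻¹) with per-row metadata (`sample_id`,
`patient_id`, `group ∈ {CR, NR, UNKNOWN}`). Grids are never resampled
implicitly; `align_to_grid` performs explicit linear interpolation and
refuses to extrapolate. Files are TSV: portability and diff-ability matter
more than compactness at this scale (~25 MB for 657 × 1761 doubles printed
at full precision).

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes —
not an optical instrument. Per cell:

    spectrum = c · S  +  baseline  +  g · glass  +  ε

* **Pure spectra `S`** — four components (protein, lipid–carbohydrate,
  nucleic acid, mixed), each a sum of lorentzian bands (FWHM 12 cm⁻¹
  default, the typical Raman linewidth) at the standard biomolecular band
  positions (785 cm⁻¹ nucleic-acid ring breathing, 1003 cm⁻¹
  phenylalanine, 1445 cm⁻¹ CH₂ deformation, …), max-normalized.
* **Concentrations `c`** — hierarchical and positive:
  `c = mean_conc(group) × patient_effect × cell_effect`, with lognormal
  multiplicative effects of unit mean and CV 0.10 (between patients) and
  0.15 (between cells). Lognormal keeps concentrations positive and is the
  standard positive-support heterogeneity model; the CVs are chosen once as
  realistic single-cell biochemical variability (tens of percent within a
  donor, smaller between donors of one group).
* **Group contrast** — protein +30% in CR; lipid–carbohydrate and nucleic
  acid +30% in NR. Direction reflects the biology the pipeline is meant to
  detect; the magnitude is a calibrated default placing ten-fold
  cross-validated PCA-LDA accuracy near 0.9 (the high-discrimination regime
  this assay reports), and is configuration, not a biological claim.
* **Interferents** — a broad fluorescence baseline
  `A·(c₀ + c₁t + c₂t²)` with randomized coefficients (amplitude 1.0,
  comparable to the signal; downward drift; curvature capped so its second
  finite difference is analytically bounded), a deterministic glass
  reference (mixture of ≥300 cm⁻¹-wide gaussians) scaled per cell
  (mean 0.5, CV 0.2), and i.i.d. gaussian channel noise (σ = 0.01 against
  unit-scale peaks).
* **Cohort shape** — 9 patients per group, 335 CR / 322 NR cells by
  default, distributed as evenly as integer division allows.

Everything is deterministic given the config seed, and the ground truth
(concentrations, pure spectra, baselines, glass scales) is retained.

**What the generator does not model:** cosmic-ray spikes, wavenumber
miscalibration, detector nonlinearity, focal-plane variation, batch
effects, or any real biochemical covariance structure between components.
Passing recovery tests therefore demonstrates the pipeline's correctness
under its own assumptions — bilinear mixing plus smooth additive
interferents — not its performance on any real instrument's output.

## Preprocessing

Order is fixed: S-G denoise → glass removal → baseline correction →
min-max normalization, then cropping to 600–1800 cm⁻¹ (normalization
before cropping; with the default grid already spanning the fingerprint
region the crop is the identity).

* **Savitzky-Golay** (order 3, window 25 channels): exact on cubics, edge
  windows handled by truncated polynomial fits. `select_sg_window` picks
  the RMSE-minimizing window against an explicit clean reference (ties to
  the smallest window); since real data lacks a clean reference, the fixed
  (25, 3) default is the pipeline setting and window selection is a
  synthetic-calibration tool.
* **Glass removal**: cell and reference spectra are decomposed with `sym4`
  (an 8-tap symmetric wavelet) to the deepest level available, capped at 7
  (≈ 87 cm⁻¹ coarse-band resolution on the default grid). The cell's
  approximation band is regressed onto the reference's approximation band.
  A single-coefficient fit proved badly biased: densely packed lorentzian
  bands leave a broad envelope in the coarse band that aliases into the
  glass estimate (~70% mean relative error on realistic cells). The
  regression therefore includes a quadratic nuisance polynomial that
  absorbs the peak envelope and any fluorescence pedestal; the glass
  coefficient is constrained non-negative (NNLS) and the test suite checks
  scale recovery within 10% across 20 seeded fixtures.
* **Baseline correction**: the spectrum is smoothed once with a moving
  average (window = knot interval, default 150 channels ≈ 102 cm⁻¹); each
  round takes the per-interval minima of the working curve as knots, fits
  a natural cubic spline, and suppresses points above it; iteration stops
  when the baseline changes < 0.1% (relative L2) or after 20 rounds.
  Smoothing once rather than every round is deliberate: re-smoothing the
  suppressed curve compounds the moving average's downward bias in concave
  regions and makes the baseline dig below a genuinely smooth background.
  The corrected spectrum is clipped at zero so non-negativity-constrained
  MCR downstream stays well-posed.
* **Min-max normalization** maps each cell to [0, 1]; constant spectra are
  a contract violation, not silently passed through.

## PCA-LDA classification

PCA is mean-centred SVD on the covariance scale (channels are already
commensurate after min-max normalization); loadings carry a deterministic
sign (largest-magnitude element positive). Component count is the smallest
`k` with cumulative explained variance > 0.90. The discriminant is the
two-class Fisher direction with pseudo-inverse fallback for singular
within-class scatter; the decision threshold sits at the midpoint of the
projected class means (equal priors — group sizes are near-balanced and
toy cases become exact). Higher LD1 score = more NR-like.

Cross-validation is stratified, shuffled with a logged seed, and refits
**everything** — PCA, component selection, LDA — inside each training
fold, so component selection cannot leak. Metrics and the ROC come from
pooled out-of-fold scores (the pooled-vs-fold-averaged choice is
documented here because either is defensible; pooling uses every sample
exactly once). When samples are fewer than channels the PCA inside CV uses
the n × n Gram-matrix eigendecomposition and reconstructs only the
retained loadings — algebraically identical to the SVD and several times
faster.

AUC is the tie-corrected Mann-Whitney statistic (`(R₁ − n₁(n₁+1)/2)/n₁n₀`,
half-credit for ties), cross-checked in the tests against an exhaustive
pairwise oracle. The permutation test shuffles labels, reruns the full
cross-validated pipeline per permutation, and reports the add-one p-value
`(1 + #{AUC_null ≥ AUC_obs})/(1 + B)`, which can never be zero.

Patient-level aggregation averages each patient's cells into one spectrum
(mixed group labels within a patient are an error), the guard against
pseudoreplication when cells per patient number in the dozens.

## MCR-ALS

The bilinear model `X ≈ C·S` is fit by alternating **exact** non-negative
least squares: every row of `C` and column of `S` is an NNLS subproblem
solved to optimality (implementation detail: unconstrained least squares
first, NNLS re-solve only where negativity appears — same solution, much
faster). Exact subproblem solves guarantee the residual is monotone
non-increasing, which the tests assert per iteration. Convergence is a
< 0.1% relative change of the residual standard deviation
`‖X − CS‖_F / √(elements)`, capped at 50 iterations.

Rank is suggested at the largest elbow (maximum second difference) of the
log singular-value spectrum and is overridable; k = 4 is the documented
reproduction setting for the four biochemical components. Initialization
is SIMPLISMA in the classical determinant formulation with channels as
variables (spectral-direction mode): purity `σ_j/(μ_j + α)` with
`α = 10%·max(μ)`, deflated after each pick by the determinant-based
independence weight; the chosen channels' intensity columns are the
initial concentration profiles and `S_init` is their least-squares
spectral estimate, clipped at zero. Scale ambiguity is fixed by
max-normalizing `S` rows (scale absorbed into `C`); components are
reported in descending total-concentration order, and `match_components`
resolves the remaining permutation ambiguity against a reference by
maximal total cosine similarity (exhaustive for k ≤ 6).

## Peak statistics

Peak intensity is the windowed maximum within ±5 cm⁻¹ of the nominal
center — robust to small calibration shifts; the window means a band can
pick up a close neighbour from another component, which is visible in the
synthetic peak tables (e.g. a nominal nucleic-acid band at 747 cm⁻¹
reading a 749 cm⁻¹ protein band). Group comparison: Shapiro-Wilk on each
group and a two-sided F-ratio variance check, both at α = 0.05; all pass →
unpaired equal-variance t-test, otherwise two-sided Mann-Whitney U with
tie correction. The F-ratio (rather than Levene) is the simplest
two-group homogeneity check and is isolated behind `group_compare` for
swapping. Pre-testing keeps the empirical type-I rate near nominal
(measured within [0.025, 0.075] at n = 9 per group in the acceptance
suite). Per-peak ROC is oriented so AUC ≥ 0.5 with the carrying group
reported; note the folded null expectation is ≈ 0.61, not 0.5, at n = 9
per group.

## Problem sizes and runtime

Defaults in tests and the acceptance script: the full cohort (657 cells ×
1761 channels) for the classifier-regime and acceptance runs; 200 × 1761
for the ten-seed MCR recovery suite; 99 permutations for the permutation
analyses (the reduced-scale demonstration setting; the 1000-permutation
default remains available in the API and CLI). The complete test suite
runs in roughly two minutes and the acceptance script in roughly two
minutes on a single CPU.

## Known limitations

* MCR-ALS rotational ambiguity is not bounded (no MCR-BANDS); recovery
  claims rest on the synthetic ground truth and cosine matching.
* The glass-removal regression assumes the substrate shape is the supplied
  reference up to scale; wavelength-dependent substrate variation is not
  modelled.
* The baseline algorithm's knot interval is a fixed channel count; heavily
  peak-crowded regions wider than the interval can lift the baseline.
* `group_compare`'s two-stage testing is the documented field convention,
  not an optimal procedure; its calibration is verified empirically at the
  study's sample size only.
* The CLI persists models as plain TSV for transparency, without schema
  versioning.
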