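# ramancell

Single-cell Raman spectral fingerprinting of induction-therapy response in
acute myeloid leukemia (AML): a tested, reusable pipeline for spectral
preprocessing, PCA-LDA classification, and MCR-ALS pure-component
resolution, with a synthetic-data generator that emulates bone-marrow
single-cell spectra and retains ground truth for recovery testing.

## The problem

Raman micro-spectroscopy records a per-cell vibrational fingerprint over
the 600–1800 cm⁻¹ region where nucleic-acid, protein, lipid and
carbohydrate bands concentrate. Given single-cell spectra from patients who
did (CR, complete remission) or did not (NR) respond to induction
chemotherapy, the analysis asks two questions:

1. **Can the response group be predicted from the fingerprint?**
   Mean-centred PCA reduces the cells × channels matrix `X` to scores
   `T = (X − x̄)·Vᵀ`, keeping the smallest `k` components whose cumulative
   explained variance exceeds 90%; a Fisher linear discriminant
   `w ∝ S_w⁻¹(μ_NR − μ_CR)` on the retained scores gives a one-dimensional
   decision axis (LD1), evaluated by stratified ten-fold cross-validation
   (components re-selected inside every training fold), ROC/AUC, a
   1000-permutation label test, and confusion-matrix metrics.
2. **Which biochemical components drive the difference?** MCR-ALS
   factorizes `X ≈ C·S` with `C ≥ 0` (cells × components concentrations)
   and `S ≥ 0` (pure component spectra), rank suggested by the elbow of the
   singular-value spectrum, initial `S` from SIMPLISMA pure-variable
   selection (10% noise level), alternating exact non-negative least
   squares (≤50 iterations, 0.1% relative change of the residual standard
   deviation). Component abundances are then compared between groups, as
   are individual characteristic peaks at patient level (Student's t or
   Mann-Whitney U, chosen by Shapiro-Wilk normality and an F-ratio variance
   check).

Raw spectra are first cleaned with the four-step chain: Savitzky-Golay
denoising (order 3, window 25) → DWT-based glass-substrate subtraction →
iterative equal-interval cubic-spline fluorescence-baseline correction →
min-max normalization, followed by cropping to the fingerprint region.

## Worked example

```bash
python examples/simulate_and_classify.py
```

```
cohort: 120 cells, 1761 channels
retained PCs at >90% cumulative variance: 3
cross-validated accuracy:    0.9500
cross-validated sensitivity: 0.9500  (NR correctly flagged)
cross-validated specificity: 0.9500  (CR correctly flagged)
cross-validated AUC:         0.9861
```

The generator plants a +30% concentration contrast (protein elevated in CR;
lipid–carbohydrate and nucleic acid elevated in NR) beneath a fluorescence
baseline, a glass background and channel noise; the numbers above show the
classifier recovering that contrast from preprocessed spectra. The other
examples resolve pure components with MCR-ALS (`resolve_components.py`,
cosines > 0.999 to the generating spectra), build the patient-level peak
table (`peak_statistics.py`), and walk one spectrum through the
preprocessing stages (`preprocess_one_spectrum.py`).

A `ramancell` command wires the same stages for shell use:

```bash
ramancell run --seed 5 --outdir out/          # simulate → preprocess → crossval
ramancell mcr --matrix out/preprocess/matrix.tsv --meta out/preprocess/meta.tsv \
    --k 4 --outdir out/mcr
```

All files are tab-separated text (matrix: one header row of wavenumbers,
then `sample_id` + intensities per row; manifest: `sample_id`, `patient_id`,
`group`).

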