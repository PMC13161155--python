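"""Generate a synthetic single-cell cohort and cross-validate the PCA-LDA classifier.

Builds a reduced cohort (4 patients and 60 cells per response group) under the
default study conditions, runs the four-step preprocessing chain, and reports
stratified ten-fold cross-validation metrics.
"""

import ramancell as rc

cfg = rc.SyntheticConfig(n_patients=4, cells_per_group={"CR": 60, "NR": 60}, seed=7)
dataset, truth = rc.simulate_dataset(cfg)
glass = rc.render_glass_reference(cfg.grid)
processed, report = rc.preprocess_pipeline(dataset, glass)

model = rc.fit_pca_lda(processed, processed.groups)
cm, roc = rc.cross_validate(processed, processed.groups, folds=10, seed=7)

print(f"cohort: {dataset.n_samples} cells, {dataset.n_channels} channels")
print(f"retained PCs at >90% cumulative variance: {model.n_components}")
print(f"cross-validated accuracy:    {cm.accuracy:.4f}")
print(f"cross-validated sensitivity: {cm.sensitivity:.4f}  (NR correctly flagged)")
print(f"cross-validated specificity: {cm.specificity:.4f}  (CR correctly flagged)")
print(f"cross-validated AUC:         {roc.auc:.4f}")
# accuracy near 0.9 and AUC above 0.95 mean the configured +30% concentration
# contrast between response groups is readily recovered from the spectra
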