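"""Patient-level characteristic-peak statistics and per-peak ROC.

Aggregates each patient's cells into one mean spectrum (avoiding
pseudoreplication), then tests every characteristic band for a group
difference with the normality/variance-driven t vs Mann-Whitney rule and
scores its discrimination with an oriented ROC AUC.
"""

import ramancell as rc

cfg = rc.SyntheticConfig(seed=13)
dataset, _ = rc.simulate_dataset(cfg)
glass = rc.render_glass_reference(cfg.grid)
processed, _ = rc.preprocess_pipeline(dataset, glass)

patients = rc.patient_mean_spectra(processed)
print(f"{patients.n_samples} patients ({(patients.groups == 'CR').sum()} CR, "
      f"{(patients.groups == 'NR').sum()} NR)")

table = rc.build_peak_table(patients)
cols = ["center", "class", "p_value", "test_used", "stars", "auc", "higher_in"]
print(table[cols].to_string(index=False, float_format=lambda v: f"{v:.4f}"))
# low p-values / high AUCs concentrate on bands of the components whose
# concentrations differ between groups; 'higher_in' names the elevated group
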