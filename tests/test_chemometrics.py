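import numpy as np
import pytest

import ramancell as rc
from ramancell import chemometrics as chem
from ramancell.errors import DataError, LabelError, ParameterError


def brute_force_auc(scores, labels, positive="NR"):
    """Exhaustive pairwise-comparison AUC estimator (independent oracle)."""
    s = np.asarray(scores, float)
    y = np.asarray(labels)
    pos = s[y == positive]
    neg = s[y != positive]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestFitPCA:
    def test_collinear_points_are_rank_one(self):
        t = np.linspace(0, 1, 30)
        X = np.column_stack([t, 2 * t])
        m = rc.fit_pca(X)
        np.testing.assert_allclose(m.explained_variance_ratio, [1.0, 0.0], atol=1e-12)

    def test_isotropic_cloud_splits_evenly(self):
        X = np.random.default_rng(0).normal(size=(10000, 2))
        m = rc.fit_pca(X)
        np.testing.assert_allclose(m.explained_variance_ratio, [0.5, 0.5], atol=0.02)

    def test_ratios_sum_to_one_and_loadings_orthonormal(self):
        X = np.random.default_rng(1).normal(size=(40, 12))
        m = rc.fit_pca(X)
        assert m.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-10)
        gram = m.loadings @ m.loadings.T
        np.testing.assert_allclose(gram, np.eye(gram.shape[0]), atol=1e-8)

    def test_full_reconstruction(self):
        X = np.random.default_rng(2).normal(size=(25, 10))
        m = rc.fit_pca(X)
        Xc = X - m.mean_spectrum
        recon = (Xc @ m.loadings.T) @ m.loadings
        np.testing.assert_allclose(recon, Xc, atol=1e-8 * np.abs(Xc).max())

    def test_single_sample_rejected(self):
        with pytest.raises(DataError):
            rc.fit_pca(np.ones((1, 5)))

    def test_gram_fast_path_matches_full_svd(self):
        X = np.random.default_rng(3).normal(size=(20, 50))
        pca_full = rc.fit_pca(X)
        pca_fast, k = chem._pca_retained(X, 0.90)
        np.testing.assert_allclose(
            pca_fast.explained_variance_ratio,
            pca_full.explained_variance_ratio[: len(pca_fast.explained_variance_ratio)],
            atol=1e-10,
        )
        np.testing.assert_allclose(
            np.abs(pca_fast.loadings), np.abs(pca_full.loadings[:k]), atol=1e-8
        )


class TestSelectNComponents:
    @pytest.mark.parametrize(
        "evr,threshold,expected",
        [
            ([0.5, 0.3, 0.15, 0.05], 0.90, 3),
            ([0.91, 0.05, 0.04], 0.90, 1),
            ([0.4, 0.3, 0.2, 0.1], 0.999, 4),
        ],
    )
    def test_cases(self, evr, threshold, expected):
        assert rc.select_n_components(np.array(evr), threshold) == expected

    @pytest.mark.parametrize("threshold", [0.0, 1.0, -0.2, 1.5])
    def test_bad_threshold_rejected(self, threshold):
        with pytest.raises(ParameterError):
            rc.select_n_components(np.array([0.9, 0.1]), threshold)


class TestFitLDA:
    def _clouds(self, sep, n=200, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.normal([0, 0], 1.0, size=(n, 2))
        b = rng.normal([sep, 0], 1.0, size=(n, 2))
        X = np.vstack([a, b])
        y = np.array(["CR"] * n + ["NR"] * n)
        return X, y

    def test_separable_clouds_perfectly_classified(self):
        X, y = self._clouds(sep=10.0)
        m = rc.fit_lda(X, y)
        acc = np.mean(m.predict(X) == y)
        assert acc == 1.0

    def test_label_swap_negates_direction(self):
        X, y = self._clouds(sep=3.0)
        m1 = rc.fit_lda(X, y)
        swapped = np.where(y == "CR", "NR", "CR")
        m2 = rc.fit_lda(X, swapped)
        np.testing.assert_allclose(m2.weights, -m1.weights, atol=1e-10)
        assert np.mean(m1.predict(X) == y) == pytest.approx(
            np.mean(m2.predict(X) == swapped)
        )

    def test_null_relabeling_near_chance(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(400, 2))
        y = np.where(rng.uniform(size=400) < 0.5, "CR", "NR")
        m = rc.fit_lda(X, y)
        assert np.mean(m.predict(X) == y) == pytest.approx(0.5, abs=0.1)

    def test_single_class_rejected(self):
        with pytest.raises(LabelError):
            rc.fit_lda(np.ones((4, 2)), np.array(["CR"] * 4))


class TestFitPCALDA:
    def test_retained_components_monotone_in_threshold(self, clean_cohort):
        ds, _ = clean_cohort
        lo = rc.fit_pca_lda(ds, ds.groups, var_threshold=0.90)
        hi = rc.fit_pca_lda(ds, ds.groups, var_threshold=0.999)
        assert hi.n_components >= lo.n_components

    def test_training_accuracy_at_least_cross_validated(self, clean_cohort):
        ds, _ = clean_cohort
        model = rc.fit_pca_lda(ds, ds.groups)
        train_acc = np.mean(rc.predict(model, ds) == ds.groups)
        cm, _ = rc.cross_validate(ds, ds.groups, folds=5, seed=1)
        assert train_acc >= cm.accuracy - 1e-12


class TestDecisionScores:
    def test_class_means_straddle_threshold(self, clean_cohort):
        ds, _ = clean_cohort
        model = rc.fit_pca_lda(ds, ds.groups)
        sc = rc.decision_scores(model, ds)
        assert sc[ds.groups == "NR"].mean() > model.lda.threshold
        assert sc[ds.groups == "CR"].mean() < model.lda.threshold

    def test_duplicated_sample_scores_identically(self, clean_cohort):
        ds, _ = clean_cohort
        model = rc.fit_pca_lda(ds, ds.groups)
        row = ds.matrix[[0, 0]]
        sc = rc.decision_scores(model, row)
        assert sc[0] == sc[1]

    def test_channel_mismatch_rejected(self, clean_cohort):
        ds, _ = clean_cohort
        model = rc.fit_pca_lda(ds, ds.groups)
        with pytest.raises(rc.errors.AlignmentError):
            rc.decision_scores(model, ds.matrix[:, :-5])


class TestCrossValidate:
    def test_separable_data_perfect_metrics(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.1, size=(30, 6))
        b = rng.normal(5, 0.1, size=(30, 6))
        X = np.vstack([a, b])
        y = np.array(["CR"] * 30 + ["NR"] * 30)
        cm, roc = rc.cross_validate(X, y, folds=5, seed=0)
        assert cm.accuracy == 1.0
        assert roc.auc == 1.0

    def test_seed_determinism(self, clean_cohort):
        ds, _ = clean_cohort
        r1 = rc.cross_validate(ds, ds.groups, folds=5, seed=3)
        r2 = rc.cross_validate(ds, ds.groups, folds=5, seed=3)
        assert r1[0] == r2[0]
        assert r1[1].auc == r2[1].auc

    def test_class_smaller_than_folds_rejected(self):
        X = np.random.default_rng(0).normal(size=(8, 3))
        y = np.array(["CR"] * 5 + ["NR"] * 3)
        with pytest.raises(DataError):
            rc.cross_validate(X, y, folds=5, seed=0)


class TestROCAUC:
    def test_perfect_ranking(self):
        roc = rc.roc_auc([0.9, 0.8, 0.2, 0.1], ["NR", "NR", "CR", "CR"])
        assert roc.auc == 1.0

    def test_all_ties_give_half(self):
        roc = rc.roc_auc([0.5] * 6, ["NR"] * 3 + ["CR"] * 3)
        assert roc.auc == 0.5

    def test_label_inversion_symmetry(self):
        rng = np.random.default_rng(4)
        s = rng.normal(size=30)
        y = np.where(rng.uniform(size=30) < 0.4, "NR", "CR")
        if len(set(y)) < 2:
            y[0] = "NR"
            y[1] = "CR"
        inv = np.where(y == "NR", "CR", "NR")
        assert rc.roc_auc(s, y).auc == pytest.approx(1 - rc.roc_auc(s, inv).auc)

    def test_matches_exhaustive_pairwise_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            n = int(rng.integers(4, 51))
            scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
            labels = np.where(rng.uniform(size=n) < 0.5, "NR", "CR")
            if len(set(labels.tolist())) < 2:
                labels[0], labels[1] = "NR", "CR"
            assert rc.roc_auc(scores, labels).auc == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12
            )

    def test_single_class_rejected(self):
        with pytest.raises(LabelError):
            rc.roc_auc([1.0, 2.0], ["CR", "CR"])


class TestConfusionMetrics:
    def test_external_validation_arithmetic(self):
        cm = rc.confusion_metrics(tp=93, fp=8, tn=92, fn=2)
        assert cm.accuracy == pytest.approx(185 / 195)
        assert cm.sensitivity == pytest.approx(93 / 95)
        assert cm.specificity == pytest.approx(92 / 100)

    def test_perfect_counts(self):
        cm = rc.confusion_metrics(tp=1, fp=0, tn=1, fn=0)
        assert cm.accuracy == cm.sensitivity == cm.specificity == 1.0

    def test_zero_denominator_flags_nan(self):
        cm = rc.confusion_metrics(tp=0, fp=1, tn=3, fn=0)
        assert np.isnan(cm.sensitivity)
        assert cm.specificity == 0.75


@pytest.fixture(scope="module")
def separable():
    rng = np.random.default_rng(0)
    X = np.vstack(
        [rng.normal(0, 0.2, size=(40, 5)), rng.normal(4, 0.2, size=(40, 5))]
    )
    y = np.array(["CR"] * 40 + ["NR"] * 40)
    return X, y


class TestPermutationTest:
    def test_strong_contrast_yields_minimal_p(self, separable):
        X, y = separable
        res = rc.permutation_test(X, y, n_permutations=19, seed=2, folds=5)
        assert res.p_value == pytest.approx(1 / 20)
        assert res.observed_auc == 1.0

    def test_seed_determinism(self, separable):
        X, y = separable
        a = rc.permutation_test(X, y, n_permutations=9, seed=5, folds=5)
        b = rc.permutation_test(X, y, n_permutations=9, seed=5, folds=5)
        np.testing.assert_array_equal(a.null_aucs, b.null_aucs)

    def test_zero_permutations_rejected(self, separable):
        X, y = separable
        with pytest.raises(ParameterError):
            rc.permutation_test(X, y, n_permutations=0, seed=0)


class TestPatientAggregation:
    def test_duplicate_spectra_average_to_themselves(self, tiny_set):
        ds = rc.SpectraSet(
            tiny_set.wavenumbers,
            np.vstack([tiny_set.matrix[0], tiny_set.matrix[0]]),
            [
                rc.SampleMeta("a", "p1", "CR"),
                rc.SampleMeta("b", "p1", "CR"),
            ],
        )
        out = rc.patient_mean_spectra(ds)
        assert out.n_samples == 1
        np.testing.assert_array_equal(out.matrix[0], tiny_set.matrix[0])

    def test_eighteen_patients_in_eighteen_rows_out(self):
        cfg = rc.SyntheticConfig(
            grid=np.linspace(600, 1800, 60),
            cells_per_group={"CR": 20, "NR": 20},
            seed=1,
        )
        ds, _ = rc.simulate_dataset(cfg)
        out = rc.patient_mean_spectra(ds)
        assert out.n_samples == 18
        np.testing.assert_array_equal(out.wavenumbers, ds.wavenumbers)

    def test_mixed_groups_within_patient_rejected(self, tiny_set):
        ds = rc.SpectraSet(
            tiny_set.wavenumbers,
            tiny_set.matrix[:2],
            [rc.SampleMeta("a", "p1", "CR"), rc.SampleMeta("b", "p1", "NR")],
        )
        with pytest.raises(DataError):
            rc.patient_mean_spectra(ds)


class TestLD1Contributions:
    def test_sum_to_one(self, clean_cohort):
        ds, _ = clean_cohort
        model = rc.fit_pca_lda(ds, ds.groups)
        contrib = rc.ld1_pc_contributions(model)
        assert contrib.sum() == pytest.approx(1.0)
        assert np.all(contrib >= 0)

    def test_single_pc_model(self):
        rng = np.random.default_rng(0)
        t = rng.normal(size=40)
        X = np.column_stack([t, t * 2, t * 3]) + rng.normal(0, 1e-6, (40, 3))
        y = np.where(t > 0, "NR", "CR")
        model = rc.fit_pca_lda(X, y, var_threshold=0.9)
        assert model.n_components == 1
        np.testing.assert_allclose(rc.ld1_pc_contributions(model), [1.0])
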