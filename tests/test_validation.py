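"""Classification metrics, CV, resampling, correlation inference, rules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from protraj.gmlvq import GMLVQ, GMLVQClassifier
from protraj.validation import (adjusted_correlation, classification_metrics,
                                exclude_outliers, fisher_r_to_z, group_compare,
                                kfold_cv, pearson_ci, positivity_threshold,
                                random_resampling, rate_of_change, steiger_z)
from protraj.validation import metrics_from_rates


class TestClassificationMetrics:
    def test_published_rate_identities_cognitive(self):
        m = metrics_from_rates(tpr=84.9, tnr=79.8, n_positive=54, n_negative=113)
        assert abs(m.macro_averaged_error - 17.6) <= 0.05 + 1e-12
        assert abs(m.accuracy - 81.4) <= 0.05 + 1e-12

    def test_published_rate_identities_biological(self):
        m = metrics_from_rates(tpr=81.1, tnr=82.3, n_positive=54, n_negative=113)
        assert abs(m.macro_averaged_error - 18.3) <= 0.05 + 1e-12
        assert abs(m.accuracy - 81.9) <= 0.05 + 1e-12

    def test_perfect_predictions(self):
        y = ["stable"] * 3 + ["progressive"] * 2
        m = classification_metrics(y, y)
        assert m.accuracy == 100.0
        assert m.macro_averaged_error == 0.0

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            classification_metrics(["stable"] * 4, ["stable"] * 4)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=4, max_size=40))
    def test_mae_identity_always_holds(self, pairs):
        true = ["progressive" if t else "stable" for t, _ in pairs]
        pred = ["progressive" if p else "stable" for _, p in pairs]
        if len(set(true)) < 2:
            true[0] = "stable" if true[0] == "progressive" else "progressive"
        true, pred = np.array(true), np.array(pred)
        m = classification_metrics(true, pred)
        assert m.macro_averaged_error == pytest.approx(
            100.0 - (m.true_positive_rate + m.true_negative_rate) / 2.0)
        for v in (m.accuracy, m.macro_averaged_error,
                  m.true_positive_rate, m.true_negative_rate):
            assert 0.0 <= v <= 100.0


class TestKFoldCV:
    def test_separable_data_high_accuracy(self, separable_classes):
        X, y = separable_classes
        cv = kfold_cv(X, y, lambda **p: GMLVQClassifier(**p), k=5, seed=0)
        assert cv.mean_metrics.accuracy >= 95.0

    def test_permuted_labels_near_chance(self, separable_classes):
        X, y = separable_classes
        rng = np.random.default_rng(0)
        accs = []
        for rep in range(5):
            yp = rng.permutation(y)
            cv = kfold_cv(X, yp, lambda **p: GMLVQClassifier(**p), k=5, seed=rep)
            accs.append(cv.mean_metrics.accuracy)
        # binomial sd of accuracy at chance with n=200 is ~3.5%; average of
        # 5 repeats should sit well inside 50 +/- 3 sd of the mean
        assert abs(np.mean(accs) - 50.0) < 3 * 3.6 / np.sqrt(5) + 5

    def test_matches_manual_fold_enumeration(self):
        # deterministic nearest-centroid model: re-derive the per-fold
        # metrics by hand over the same stratified splits
        from sklearn.model_selection import StratifiedKFold
        from sklearn.neighbors import NearestCentroid

        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(0, 1, (10, 2)), rng.normal(3, 1, (10, 2))])
        y = np.array(["stable"] * 10 + ["progressive"] * 10)
        cv = kfold_cv(X, y, lambda **p: NearestCentroid(), k=5, seed=4)
        accs = []
        for tr, te in StratifiedKFold(5, shuffle=True, random_state=4).split(X, y):
            pred = NearestCentroid().fit(X[tr], y[tr]).predict(X[te])
            accs.append(100.0 * np.mean(pred == y[te]))
        assert cv.mean_metrics.accuracy == pytest.approx(np.mean(accs))

    def test_hyperparameter_grid_selection_runs(self, separable_classes):
        X, y = separable_classes
        idx = np.array(list(range(30)) + list(range(100, 130)))
        grid = [{"alpha_w": 0.05, "alpha_omega": 0.01},
                {"alpha_w": 0.01, "alpha_omega": 0.001}]
        cv = kfold_cv(X[idx], y[idx],
                      lambda **p: GMLVQClassifier(**p, max_epochs=60),
                      k=3, hyperparam_grid=grid, seed=1)
        assert len(cv.chosen_params) == 3
        assert all(p in grid for p in cv.chosen_params)


class TestRandomResampling:
    def test_recovers_population_correlation(self, default_cohort):
        lab = default_cohort.labelled
        feats = ["gds", "adni_mem", "adni_ef"]
        X = lab[feats].to_numpy(float)
        y = lab["label"].to_numpy()
        slopes = lab["true_slope"].to_numpy()
        res = random_resampling(X, y, slopes, n_resamples=50, train_size=52,
                                seed=0, feature_names=feats)
        # large-n oracle for the population value: train once on the full
        # labelled sample, project a fresh large cohort, correlate
        from protraj.simulate import SimulationConfig, simulate_cohort

        big = simulate_cohort(SimulationConfig(
            seed=99, n_subjects=1200, grid_shape=(6, 6, 6),
            region_center=(3, 3, 3), region_radius=1.5)).labelled
        model = GMLVQ(X, y, feature_names=feats).fit(seed=0)
        r_oracle, _ = stats.pearsonr(model.project(big[feats].to_numpy(float)),
                                     big["true_slope"].to_numpy())
        assert res.median_r < 0.0
        assert res.median_r == pytest.approx(r_oracle, abs=0.15)

    def test_null_slopes_ci_covers_zero(self, default_cohort):
        lab = default_cohort.labelled
        feats = ["gds", "adni_mem", "adni_ef"]
        rng = np.random.default_rng(1)
        slopes = rng.normal(size=len(lab))  # independent of everything
        res = random_resampling(lab[feats].to_numpy(float), lab["label"].to_numpy(),
                                slopes, n_resamples=50, train_size=52, seed=2,
                                feature_names=feats)
        lo, hi = res.ci95
        assert lo < 0.0 < hi

    def test_single_resample_returns_its_model(self, default_cohort):
        lab = default_cohort.labelled
        feats = ["gds", "adni_mem", "adni_ef"]
        res = random_resampling(lab[feats].to_numpy(float), lab["label"].to_numpy(),
                                lab["true_slope"].to_numpy(), n_resamples=1,
                                train_size=52, seed=3, feature_names=feats)
        assert len(res.test_correlations) == 1
        assert res.median_r == res.test_correlations[0]
        assert res.median_model is not None


class TestRateOfChange:
    def test_exact_line(self):
        t = np.array([0.0, 1.0, 2.0])
        assert rate_of_change(t, 1 + 2 * t).slope == pytest.approx(2.0)

    def test_constant_series(self):
        assert rate_of_change([0, 1, 2], [5, 5, 5]).slope == pytest.approx(0.0)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(0)
        t = np.sort(rng.uniform(0, 4, 6))
        s = 1.0 - 0.3 * t + rng.normal(0, 0.1, 6)
        tc = t - t.mean()
        oracle = (tc @ (s - s.mean())) / (tc @ tc)
        assert rate_of_change(t, s).slope == pytest.approx(oracle, abs=1e-10)

    def test_too_few_timepoints(self):
        with pytest.raises(ValueError, match="3 timepoints"):
            rate_of_change([0, 1], [1, 2])


class TestExcludeOutliers:
    def test_all_equal_nothing_excluded(self):
        proj = np.zeros(8)
        labels = ["stable"] * 4 + ["progressive"] * 4
        kept, log = exclude_outliers(proj, labels)
        assert len(kept) == 8
        assert log.empty

    def test_extreme_stable_subject_excluded(self):
        rng = np.random.default_rng(0)
        proj = np.concatenate([rng.normal(0, 1, 30), rng.normal(1, 1, 30)])
        labels = np.array(["stable"] * 30 + ["progressive"] * 30)
        mu, sd = proj[:30].mean(), proj[:30].std()
        proj[0] = mu + 3.5 * sd
        kept, log = exclude_outliers(proj, labels)
        assert 0 not in kept
        assert 0 in log["index"].to_numpy()

    def test_matches_direct_rule_application(self):
        rng = np.random.default_rng(1)
        proj = np.concatenate([rng.normal(0, 1, 200), rng.normal(2, 1, 120)])
        labels = np.array(["stable"] * 200 + ["progressive"] * 120)
        kept, _ = exclude_outliers(proj, labels)
        s, p = proj[:200], proj[200:]
        hi = s.mean() + 2 * s.std()
        lo = p.mean() - 2 * p.std()
        manual = np.flatnonzero(~((proj > hi) | (proj < lo)))
        assert np.array_equal(kept, manual)

    def test_idempotent_under_fixed_thresholds(self):
        rng = np.random.default_rng(2)
        proj = np.concatenate([rng.normal(0, 1, 50), rng.normal(2, 1, 50)])
        labels = np.array(["stable"] * 50 + ["progressive"] * 50)
        kept, log = exclude_outliers(proj, labels)
        hi = log["upper_threshold"].iloc[0] if len(log) else np.inf
        lo = log["lower_threshold"].iloc[0] if len(log) else -np.inf
        again = kept[(proj[kept] <= hi) & (proj[kept] >= lo)]
        assert np.array_equal(again, kept)


class TestPearsonCI:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        res = pearson_ci(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)

    def test_ci_matches_bootstrap(self):
        rng = np.random.default_rng(0)
        n = 103
        x = rng.normal(size=n)
        y = 0.55 * x + rng.normal(size=n) * np.sqrt(1 - 0.55 ** 2)
        res = pearson_ci(x, y)
        boots = []
        for _ in range(10_000):
            idx = rng.integers(0, n, n)
            boots.append(np.corrcoef(x[idx], y[idx])[0, 1])
        blo, bhi = np.percentile(boots, [2.5, 97.5])
        assert res.ci95[0] == pytest.approx(blo, abs=0.03)
        assert res.ci95[1] == pytest.approx(bhi, abs=0.03)

    def test_coverage_near_nominal(self):
        rng = np.random.default_rng(1)
        cover = 0
        reps = 500
        for _ in range(reps):
            x = rng.normal(size=50)
            y = rng.normal(size=50)
            lo, hi = pearson_ci(x, y).ci95
            cover += lo <= 0.0 <= hi
        assert cover / reps == pytest.approx(0.95, abs=0.03)

    def test_ci_shrinks_with_n(self):
        widths = []
        for n in (20, 80, 320):
            # construct a sample with exactly r ~ 0.5 via population quantiles
            rng = np.random.default_rng(2)
            x = rng.normal(size=n)
            y = 0.5 * x + rng.normal(size=n) * np.sqrt(0.75)
            res = pearson_ci(x, y)
            widths.append(res.ci95[1] - res.ci95[0])
        assert widths[0] > widths[1] > widths[2]


class TestAdjustedCorrelation:
    def test_constant_covariate_equals_plain_r(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(size=30)
        c = np.full(30, 2.0)
        res = adjusted_correlation(x, y, c)
        assert res.r == pytest.approx(pearson_ci(x, y).r, abs=1e-10)

    def test_covariate_identical_to_y_gives_zero(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=40)
        y = 0.7 * x + rng.normal(size=40)
        res = adjusted_correlation(x, y, y)
        assert res.r == 0.0
        assert res.p == 1.0

    def test_matches_closed_form_partial_correlation(self):
        rng = np.random.default_rng(2)
        Z = rng.normal(size=(60, 3))
        x, y, c = Z[:, 0] + 0.4 * Z[:, 2], Z[:, 1] + 0.4 * Z[:, 2], Z[:, 2]
        res = adjusted_correlation(x, y, c)
        rxy = np.corrcoef(x, y)[0, 1]
        rxc = np.corrcoef(x, c)[0, 1]
        ryc = np.corrcoef(y, c)[0, 1]
        oracle = (rxy - rxc * ryc) / np.sqrt((1 - rxc ** 2) * (1 - ryc ** 2))
        assert res.r == pytest.approx(oracle, abs=1e-10)


class TestFisherRtoZ:
    def test_published_development_vs_validation_cognitive(self):
        z, p = fisher_r_to_z(-0.41, 167, -0.40, 126)
        assert abs(z) == pytest.approx(0.1, abs=0.01)
        assert p == pytest.approx(0.92, abs=0.01)

    def test_published_development_vs_validation_biological(self):
        z, p = fisher_r_to_z(-0.55, 167, -0.68, 126)
        assert abs(z) == pytest.approx(1.76, abs=0.01)
        assert p == pytest.approx(0.08, abs=0.005)

    def test_equal_correlations_give_zero(self):
        z, p = fisher_r_to_z(0.3, 50, 0.3, 80)
        assert z == 0.0
        assert p == pytest.approx(1.0)

    @settings(deadline=None, max_examples=50)
    @given(st.floats(-0.95, 0.95), st.floats(-0.95, 0.95),
           st.integers(5, 500), st.integers(5, 500))
    def test_antisymmetric(self, r1, r2, n1, n2):
        z12, _ = fisher_r_to_z(r1, n1, r2, n2)
        z21, _ = fisher_r_to_z(r2, n2, r1, n1)
        assert z12 == pytest.approx(-z21, abs=1e-12)

    def test_degenerate_correlation_rejected(self):
        with pytest.raises(ValueError):
            fisher_r_to_z(1.0, 50, 0.3, 50)


class TestSteigerZ:
    def test_equal_dependent_correlations_give_zero(self):
        z, p = steiger_z(0.4, 0.4, 0.6, 100)
        assert z == 0.0
        assert p == pytest.approx(1.0)

    def test_agrees_with_permutation_oracle(self):
        # exchangeability of the two predictors holds under the null after
        # standardisation; compare analytic and permutation p-values
        rng = np.random.default_rng(0)
        n = 200
        R = np.array([[1.0, 0.5, 0.4], [0.5, 1.0, 0.4], [0.4, 0.4, 1.0]])
        Z = rng.standard_normal((n, 3)) @ np.linalg.cholesky(R).T
        x1, x2, o = Z[:, 0], Z[:, 1], Z[:, 2]

        def stat(a, b):
            return np.corrcoef(a, o)[0, 1] - np.corrcoef(b, o)[0, 1]

        observed = stat(x1, x2)
        perm = np.empty(10_000)
        for i in range(10_000):
            swap = rng.uniform(size=n) < 0.5
            a = np.where(swap, x2, x1)
            b = np.where(swap, x1, x2)
            perm[i] = stat(a, b)
        p_perm = np.mean(np.abs(perm) >= abs(observed))
        _, p_analytic = steiger_z(np.corrcoef(x1, o)[0, 1], np.corrcoef(x2, o)[0, 1],
                                  np.corrcoef(x1, x2)[0, 1], n)
        assert p_analytic == pytest.approx(p_perm, abs=0.05)

    def test_non_psd_triple_rejected(self):
        with pytest.raises(ValueError, match="positive semidefinite"):
            steiger_z(0.9, -0.9, 0.9, 50)


class TestPositivity:
    def test_reference_percentile_convention(self):
        ref = np.arange(1.0, 11.0)
        thr, pos = positivity_threshold(ref, np.array([9.2, 9.0]))
        assert thr == pytest.approx(9.1)
        assert list(pos) == [True, False]

    def test_values_far_below_reference(self):
        ref = np.linspace(1.0, 2.0, 20)
        _, pos = positivity_threshold(ref, np.full(5, 0.1))
        assert not pos.any()

    def test_value_at_threshold_is_negative(self):
        ref = np.arange(1.0, 11.0)
        thr, pos = positivity_threshold(ref, np.array([9.1]))
        assert thr == pytest.approx(9.1)
        assert not pos[0]

    def test_small_reference_rejected(self):
        with pytest.raises(ValueError, match=">= 10"):
            positivity_threshold(np.arange(5.0), np.array([1.0]))


class TestGroupCompare:
    def test_identical_groups(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        t, p, d = group_compare(a, a.copy())
        assert t == pytest.approx(0.0)
        assert d == pytest.approx(0.0)

    def test_unit_effect_size(self):
        # constructed samples with means 0 and 1, common sample sd exactly 1
        base = np.array([-1.0, 0.0, 1.0])
        t, p, d = group_compare(base, base + 1.0)
        assert d == pytest.approx(-1.0)

    def test_matches_textbook_formulas(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 40), rng.normal(0.5, 1.3, 55)
        t, p, d = group_compare(a, b)
        na, nb = 40, 55
        sp = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2))
        t_oracle = (a.mean() - b.mean()) / (sp * np.sqrt(1 / na + 1 / nb))
        assert t == pytest.approx(t_oracle, abs=1e-10)
        assert d == pytest.approx((a.mean() - b.mean()) / sp, abs=1e-10)
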