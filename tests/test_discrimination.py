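import subprocess

import numpy as np
import pytest

from trnapore.discrimination import (
    AccuracyReport,
    ConfusionCounts,
    balanced_accuracy,
    compare_populations,
    crossvalidate,
    features_from_cohort,
    fit_linear_softmargin,
    population_log_stats,
)
from trnapore.synthetic_squiggle import make_two_class_cohort


class TestBalancedAccuracy:
    def test_perfect_classifier(self):
        assert balanced_accuracy(ConfusionCounts(10, 10, 10, 10)) == 1.0

    def test_always_predicts_one_class_on_balanced_data(self):
        assert balanced_accuracy(ConfusionCounts(10, 10, 10, 0)) == 0.5

    def test_worked_formula_example(self):
        assert balanced_accuracy(ConfusionCounts(10, 10, 8, 6)) == pytest.approx(0.7)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            balanced_accuracy(ConfusionCounts(0, 10, 0, 5))

    def test_equals_plain_accuracy_on_balanced_classes(self, rng):
        for _ in range(20):
            t = int(rng.integers(1, 50))
            p1 = int(rng.integers(0, t + 1))
            p2 = int(rng.integers(0, t + 1))
            ba = balanced_accuracy(ConfusionCounts(t, t, p1, p2))
            assert ba == pytest.approx((p1 + p2) / (2 * t))

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(5, 5, 6, 0)


class TestFitLinearSoftmargin:
    def test_separable_pair_is_bisected(self):
        X = np.array([[0.0, 20.0], [1.0, 30.0]])
        y = np.array([-1, 1])
        model = fit_linear_softmargin(X, y)
        assert model.predict(X).tolist() == [-1, 1]
        midpoint = X.mean(axis=0)
        assert abs(model.decision_value(midpoint[None, :])[0]) < 1e-6

    def test_separable_cloud_training_accuracy_is_one(self, rng):
        X = np.vstack(
            [
                rng.normal([0.0, 25.0], [0.1, 0.5], size=(40, 2)),
                rng.normal([2.0, 32.0], [0.1, 0.5], size=(40, 2)),
            ]
        )
        y = np.repeat([1, -1], 40)
        model = fit_linear_softmargin(X, y)
        pred = model.predict(X)
        c = ConfusionCounts(40, 40, int(np.sum(pred[:40] == 1)), int(np.sum(pred[40:] == -1)))
        assert balanced_accuracy(c) == 1.0

    def test_single_class_rejected(self):
        X = np.zeros((4, 2))
        with pytest.raises(ValueError):
            fit_linear_softmargin(X, np.ones(4))

    def test_standardize_mode_classifies_like_raw_on_separable_data(self, rng):
        X = np.vstack(
            [
                rng.normal([0.0, 25.0], [0.1, 0.5], size=(30, 2)),
                rng.normal([2.0, 32.0], [0.1, 0.5], size=(30, 2)),
            ]
        )
        y = np.repeat([1, -1], 30)
        raw = fit_linear_softmargin(X, y, standardize=False)
        std = fit_linear_softmargin(X, y, standardize=True)
        np.testing.assert_array_equal(raw.predict(X), std.predict(X))

    def test_matches_kernlab_reference_fit(self, rng, tmp_path):
        # independent oracle: kernlab's C-svc with linear (vanilladot)
        # kernel at C=10, no internal scaling, on the same points
        X = np.vstack(
            [
                rng.normal([0.3, 26.0], [0.25, 1.5], size=(25, 2)),
                rng.normal([0.55, 29.0], [0.25, 1.5], size=(25, 2)),
            ]
        )
        y = np.repeat([1, -1], 25)
        model = fit_linear_softmargin(X, y, C=10.0)
        data = tmp_path / "points.csv"
        np.savetxt(data, np.column_stack([X, y]), delimiter=",")
        script = tmp_path / "svm.R"
        script.write_text(
            'suppressMessages(library(kernlab))\n'
            f'd <- read.csv("{data}", header=FALSE)\n'
            'x <- as.matrix(d[,1:2]); y <- factor(d[,3], levels=c(1,-1))\n'
            'fit <- ksvm(x, y, type="C-svc", kernel="vanilladot", C=10, scaled=FALSE)\n'
            'w <- colSums(coef(fit)[[1]] * x[unlist(alphaindex(fit)),])\n'
            'cat(w[1], w[2], -b(fit), "\\n")\n'
        )
        try:
            out = subprocess.run(
                ["Rscript", str(script)], capture_output=True, text=True, timeout=120
            )
        except FileNotFoundError:
            pytest.skip("Rscript not available")
        assert out.returncode == 0, out.stderr
        w1, w2, b0 = map(float, out.stdout.strip().splitlines()[-1].split())
        ref = np.array([w1, w2])
        # kernlab's sign convention depends on factor-level ordering
        if float(ref @ model.weights) < 0:
            ref, b0 = -ref, -b0
        scale = np.linalg.norm(model.weights) / np.linalg.norm(ref)
        np.testing.assert_allclose(model.weights, ref * scale, rtol=0.05)
        assert model.bias == pytest.approx(b0 * scale, rel=0.05)
        ref_pred = np.where(X @ ref + b0 >= 0, 1, -1)
        agreement = np.mean(ref_pred == model.predict(X))
        assert agreement >= 0.96


class TestCrossValidate:
    def test_default_protocol_yields_250_scores(self):
        df = make_two_class_cohort(40, seed=0)
        X, y = features_from_cohort(df, "II")
        report = crossvalidate(X, y, seed=1)
        assert isinstance(report, AccuracyReport)
        assert report.scores.size == 5 * 50
        assert np.all((report.scores >= 0) & (report.scores <= 1))

    def test_fixed_seed_reproduces_report(self):
        df = make_two_class_cohort(20, seed=3)
        X, y = features_from_cohort(df, "II")
        r1 = crossvalidate(X, y, seed=9)
        r2 = crossvalidate(X, y, seed=9)
        np.testing.assert_array_equal(r1.scores, r2.scores)
        assert r1.mean == r2.mean and r1.sd == r2.sd

    def test_well_separated_cohort_scores_high(self, rng):
        X = np.vstack(
            [
                rng.normal([0.0, 20.0], [0.05, 0.2], size=(40, 2)),
                rng.normal([1.0, 30.0], [0.05, 0.2], size=(40, 2)),
            ]
        )
        y = np.repeat([1, -1], 40)
        report = crossvalidate(X, y, seed=2)
        assert report.mean >= 0.98

    def test_identical_distributions_score_at_chance(self):
        models = {
            "I": None,  # placeholder replaced below
        }
        from trnapore.synthetic_squiggle import DEFAULT_REGION_MODELS, RegionModel

        shared = DEFAULT_REGION_MODELS["II"][0]
        models = {
            "I": DEFAULT_REGION_MODELS["I"],
            "II": shared,  # same model for both classes: no signal
            "III": DEFAULT_REGION_MODELS["III"],
        }
        df = make_two_class_cohort(80, region_models=models, seed=5)
        X, y = features_from_cohort(df, "II")
        report = crossvalidate(X, y, seed=6)
        assert report.mean == pytest.approx(0.5, abs=0.1)

    def test_shuffled_labels_score_at_chance(self, rng):
        df = make_two_class_cohort(80, seed=7)
        X, y = features_from_cohort(df, "II")
        rng.shuffle(y)
        report = crossvalidate(X, y, seed=8)
        assert report.mean == pytest.approx(0.5, abs=0.1)

    def test_too_few_points_rejected(self):
        X = np.zeros((3, 2))
        y = np.array([1, -1, 1])
        with pytest.raises(ValueError):
            crossvalidate(X, y, folds=5)


class TestPopulationLogStats:
    def test_equal_values_have_zero_sem(self):
        mean, sem = population_log_stats([1e-3, 1e-3])
        assert mean == pytest.approx(-3.0)
        assert sem == 0.0

    def test_two_point_sem(self):
        mean, sem = population_log_stats([1e-2, 1e-4])
        assert mean == pytest.approx(-3.0)
        assert sem == pytest.approx(1.0)

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            population_log_stats([1e-3, 0.0])


class TestComparePopulations:
    def test_identical_samples_give_p_one(self):
        a = [1e-3, 2e-3, 3e-3]
        assert compare_populations(a, a) == pytest.approx(1.0)

    def test_degenerate_zero_variance(self):
        assert compare_populations([1e-3, 1e-3], [1e-3, 1e-3]) == 1.0
        assert compare_populations([1e-3, 1e-3], [1e-2, 1e-2]) == 0.0

    def test_distant_populations_reject_strongly(self, rng):
        a = 10 ** rng.normal(-3.2, 0.1, 100)
        b = 10 ** rng.normal(-1.2, 0.1, 100)
        assert compare_populations(a, b) < 1e-4

    def test_type_i_error_rate_near_nominal(self, rng):
        # two draws from one distribution, repeated: p rejects at 5%
        # in about 5% of trials
        from scipy import stats

        n_trials = 1000
        a = rng.normal(-2.9, 0.3, size=(n_trials, 20))
        b = rng.normal(-2.9, 0.3, size=(n_trials, 20))
        p = stats.ttest_ind(a, b, axis=1, equal_var=False).pvalue
        rate = np.mean(p < 0.05)
        assert 0.03 <= rate <= 0.07

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            compare_populations([1e-3], [1e-3, 2e-3])
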