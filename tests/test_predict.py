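"""Correlation screening, regression, stepwise LDA, LOOCV, metrics."""

import numpy as np
import pandas as pd
import pytest

from alphanft.indices import cohort_indices, cohort_mraa
from alphanft.pipeline import ecrs_wide_table
from alphanft.predict import (
    ConfusionCounts,
    ResponderLDA,
    classification_metrics,
    correlation_table,
    discriminant_score,
    fit_lda,
    loocv_validate,
    simple_linear_regression,
    stepwise_select,
)
from alphanft.simulate import SimulationConfig, generate_cohort


def exact_r_pair(r, n, rng):
    """Construct (x, y) whose sample Pearson correlation is exactly r."""
    x = rng.standard_normal(n)
    e = rng.standard_normal(n)
    x = (x - x.mean()) / x.std()
    e = e - e.mean()
    e -= x * (e @ x) / (x @ x)          # orthogonalize
    e /= e.std()
    y = r * x + np.sqrt(1 - r ** 2) * e
    return x, y


def bh_stepup_oracle(pvals):
    """Benjamini-Hochberg adjusted q-values, written from the definition."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * m / rank_from_top)
        q[i] = val
        prev = val
    return q


class TestCorrelationTable:
    def _tables(self, n=20, seed=0):
        rng = np.random.default_rng(seed)
        ecrs = pd.DataFrame(
            rng.uniform(1, 10, size=(n, 4)),
            columns=["delta", "theta", "alpha", "beta"],
            index=[f"S{i}" for i in range(n)])
        return rng, ecrs

    def test_perfect_positive_and_negative(self):
        rng, ecrs = self._tables()
        idx = pd.DataFrame({
            "L1": 2 * ecrs["alpha"] - 1,
            "L2": -ecrs["alpha"],
            "L3": rng.standard_normal(len(ecrs)),
        }, index=ecrs.index)
        table = correlation_table(ecrs, idx)
        get = lambda b, i: table.query("band==@b and index==@i")["r"].iloc[0]
        assert get("alpha", "L1") == pytest.approx(1.0)
        assert get("alpha", "L2") == pytest.approx(-1.0)
        assert len(table) == 12

    def test_bh_adjustment_matches_stepup_oracle(self):
        rng, ecrs = self._tables(seed=3)
        idx = pd.DataFrame(rng.standard_normal((len(ecrs), 3)),
                           columns=["L1", "L2", "L3"], index=ecrs.index)
        table = correlation_table(ecrs, idx)
        oracle = bh_stepup_oracle(table["p"].to_numpy())
        assert np.allclose(table["q"].to_numpy(), oracle, atol=1e-12)
        # q is monotone nondecreasing in the rank of p
        srt = table.sort_values("p")
        assert (np.diff(srt["q"]) >= -1e-12).all()

    def test_zero_variance_flagged_excluded(self):
        rng, ecrs = self._tables(seed=4)
        ecrs["beta"] = 2.0
        idx = pd.DataFrame(rng.standard_normal((len(ecrs), 3)),
                           columns=["L1", "L2", "L3"], index=ecrs.index)
        with pytest.warns(UserWarning):
            table = correlation_table(ecrs, idx)
        beta_rows = table[table["band"] == "beta"]
        assert beta_rows["r"].isna().all()
        ok = table.dropna(subset=["p"])
        assert np.allclose(ok["q"], bh_stepup_oracle(ok["p"].to_numpy()))


class TestRegression:
    def test_exact_line(self):
        x = np.arange(10.0)
        res = simple_linear_regression(x, 2 * x + 1)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)

    @pytest.mark.parametrize("r,expected_r2", [(0.64, 0.4096), (0.55, 0.3025)])
    def test_r_squared_equals_r_squared(self, r, expected_r2, rng):
        x, y = exact_r_pair(r, 46, rng)
        res = simple_linear_regression(x, y)
        assert res.r_squared == pytest.approx(expected_r2, abs=1e-12)
        assert res.r_squared == pytest.approx(
            np.corrcoef(x, y)[0, 1] ** 2, abs=1e-12)

    def test_null_r2_expectation(self):
        """E[R^2] under independence is ~1/(n-1)."""
        r = np.random.default_rng(17)
        n, reps = 46, 1000
        vals = [simple_linear_regression(r.standard_normal(n),
                                         r.standard_normal(n)).r_squared
                for _ in range(reps)]
        assert np.mean(vals) == pytest.approx(1 / (n - 1), rel=0.2)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            simple_linear_regression(np.ones(10), np.arange(10.0))


class TestLDA:
    def test_one_dim_midpoint_boundary(self, rng):
        x = np.concatenate([rng.normal(30, 2, 20), rng.normal(10, 2, 20)])
        labels = np.repeat([True, False], 20)
        model = fit_lda(x, labels)
        # decision boundary at the feature value where D = 0
        boundary = -model.intercept / model.coefficients[0]
        mids = (x[labels].mean() + x[~labels].mean()) / 2
        assert boundary == pytest.approx(mids, rel=1e-9)
        assert discriminant_score(model, np.array([25.0])) < 0  # responder side
        assert discriminant_score(model, np.array([mids])) == pytest.approx(
            0.0, abs=1e-9)

    def test_responders_score_negative_when_separable(self, rng):
        x = np.concatenate([rng.normal(30, 1, 15), rng.normal(10, 1, 15)])
        labels = np.repeat([True, False], 15)
        model = fit_lda(x, labels)
        assert (discriminant_score(model, x[labels, None]) < 0).all()
        assert (discriminant_score(model, x[~labels, None]) > 0).all()

    def test_matches_sklearn_decision_boundary(self, rng):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
        X = rng.standard_normal((60, 3))
        labels = np.r_[np.ones(25, bool), np.zeros(35, bool)]
        X[labels] += [1.0, 0.5, 0.0]
        ours = fit_lda(X, labels, priors="proportional")
        sk = LinearDiscriminantAnalysis(solver="lsqr").fit(X, labels)
        pred_ours = discriminant_score(ours, X) < 0
        assert np.array_equal(pred_ours, sk.predict(X))

    def test_affine_feature_rescale_invariance(self, rng):
        X = rng.standard_normal((40, 2))
        labels = np.r_[np.ones(18, bool), np.zeros(22, bool)]
        X[labels, 0] += 1.5
        base = discriminant_score(fit_lda(X, labels), X) < 0
        X2 = X.copy()
        X2[:, 0] = 100.0 * X2[:, 0] - 7.0
        rescaled = discriminant_score(fit_lda(X2, labels), X2) < 0
        assert np.array_equal(base, rescaled)

    def test_duplicate_feature_singularity_error(self, rng):
        x = rng.standard_normal(30)
        X = np.stack([x, x], axis=1)
        labels = np.r_[np.ones(15, bool), np.zeros(15, bool)]
        with pytest.raises(np.linalg.LinAlgError):
            fit_lda(X, labels)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_lda(rng.standard_normal(10), np.ones(10, bool))

    def test_score_arithmetic(self):
        from alphanft.predict import DiscriminantModel
        m = DiscriminantModel(("x0",), np.array([2.0]), 1.0)
        assert discriminant_score(m, np.array([3.0])) == pytest.approx(7.0)
        m2 = DiscriminantModel(("a", "b"), np.array([1.0, -1.0]), 0.0)
        assert discriminant_score(m2, np.array([4.0, 4.0])) == pytest.approx(0.0)


class TestStepwise:
    def test_informative_single_feature_selected(self, rng):
        n = 60
        labels = np.r_[np.ones(30, bool), np.zeros(30, bool)]
        X = rng.standard_normal((n, 4))
        X[labels, 2] += 2.0
        sel = stepwise_select(X, labels,
                              feature_names=["delta", "theta", "alpha", "beta"])
        assert "alpha" in sel

    def test_redundant_duplicate_enters_once(self, rng):
        n = 60
        labels = np.r_[np.ones(30, bool), np.zeros(30, bool)]
        info = rng.standard_normal(n) + 2.0 * labels
        X = np.stack([info, info.copy()], axis=1)
        sel = stepwise_select(X, labels, feature_names=["a", "a2"])
        assert sel == ["a"]  # deterministic first-column tie-break

    def test_null_features_mostly_empty(self):
        """Labels independent of features: empty selection in ~(1-alpha)^4."""
        r = np.random.default_rng(23)
        empty = 0
        reps = 200
        for _ in range(reps):
            X = r.standard_normal((46, 4))
            labels = r.random(46) < 0.8
            if min(labels.sum(), (~labels).sum()) < 2:
                continue
            if not stepwise_select(X, labels):
                empty += 1
        assert empty / reps == pytest.approx(0.95 ** 4, abs=0.08)

    def test_strong_alpha_cohorts_select_alpha(self):
        """With a strong alpha-learning link, alpha is selected essentially
        always and is usually the only feature retained."""
        alpha_in = alpha_only = 0
        reps = 60
        for seed in range(reps):
            cfg = SimulationConfig(seed=seed, ecrs_learning_correlation=0.9)
            ds = generate_cohort(cfg)
            idx = cohort_indices(cohort_mraa(ds.trial_table,
                                             ds.baseline_table))
            ecrs = ecrs_wide_table(ds.ecrs_table)
            sel = stepwise_select(ecrs.to_numpy(),
                                  idx["responder_L2"].to_numpy(),
                                  feature_names=list(ecrs.columns))
            alpha_in += "alpha" in sel
            alpha_only += sel == ["alpha"]
        assert alpha_in / reps >= 0.95
        assert alpha_only / reps >= 0.75


class TestLOOCV:
    def test_separable_data_perfect(self, rng):
        x = np.concatenate([rng.normal(40, 1, 10), rng.normal(0, 1, 10)])
        labels = np.repeat([True, False], 10)
        feats = pd.DataFrame({"alpha": x})
        counts, table = loocv_validate(feats, labels,
                                       fixed_feature_names=["alpha"])
        assert (counts.TP, counts.TN, counts.FP, counts.FN) == (10, 10, 0, 0)
        m = classification_metrics(counts)
        assert m.accuracy_pct == 100.0

    def test_each_subject_predicted_once(self, default_cohort):
        ds = default_cohort
        idx = cohort_indices(cohort_mraa(ds.trial_table, ds.baseline_table))
        ecrs = ecrs_wide_table(ds.ecrs_table)
        counts, table = loocv_validate(ecrs, idx["responder_L1"].to_numpy(),
                                       fixed_feature_names=["alpha"])
        assert len(table) == 46
        assert counts.n == 46
        assert table["subject"].is_unique

    def test_deterministic(self, rng):
        X = pd.DataFrame({"alpha": rng.standard_normal(30)})
        labels = rng.random(30) < 0.6
        a = loocv_validate(X, labels, fixed_feature_names=["alpha"])[0]
        b = loocv_validate(X, labels, fixed_feature_names=["alpha"])[0]
        assert (a.TP, a.TN, a.FP, a.FN) == (b.TP, b.TN, b.FP, b.FN)

    def test_nested_stepwise_runs(self, rng):
        n = 40
        labels = np.r_[np.ones(20, bool), np.zeros(20, bool)]
        X = pd.DataFrame(rng.standard_normal((n, 4)),
                         columns=["delta", "theta", "alpha", "beta"])
        X.loc[labels, "alpha"] += 2.5
        counts, table = loocv_validate(X, labels,
                                       selection_policy="nested_stepwise")
        assert counts.n == n
        assert classification_metrics(counts).accuracy_pct > 70.0


class TestMetrics:
    def test_reconstructed_confusion_counts(self):
        """A 38/8 responder split with sens 94.7 / spec 25.0 corresponds to
        TP=36, FN=2, TN=2, FP=6 and therefore accuracy 82.6."""
        m = classification_metrics(ConfusionCounts(TP=36, TN=2, FP=6, FN=2))
        r = m.rounded()
        assert (r.sensitivity_pct, r.specificity_pct, r.accuracy_pct) == \
            (94.7, 25.0, 82.6)

    def test_perfect(self):
        m = classification_metrics(ConfusionCounts(10, 10, 0, 0))
        assert (m.sensitivity_pct, m.specificity_pct, m.accuracy_pct) == \
            (100.0, 100.0, 100.0)

    def test_undefined_denominator_is_missing(self):
        m = classification_metrics(ConfusionCounts(TP=0, TN=5, FP=3, FN=0))
        assert np.isnan(m.sensitivity_pct)
        assert m.specificity_pct == pytest.approx(62.5)


class TestModelSurface:
    def test_fit_summary_and_loocv(self, default_cohort):
        ds = default_cohort
        idx = cohort_indices(cohort_mraa(ds.trial_table, ds.baseline_table))
        ecrs = ecrs_wide_table(ds.ecrs_table)
        res = ResponderLDA(ecrs, idx["responder_L2"]).fit(stepwise=False)
        assert res.selected_features == ["delta", "theta", "alpha", "beta"]
        text = res.summary()
        assert "accuracy" in text and "intercept" in text
        counts, metrics, table = res.loocv()
        assert counts.n == 46

    def test_empty_selection_reported_not_raised(self, rng):
        X = pd.DataFrame(rng.standard_normal((30, 4)),
                         columns=["delta", "theta", "alpha", "beta"])
        labels = np.r_[np.ones(15, bool), np.zeros(15, bool)]
        res = ResponderLDA(X, labels).fit(enter_p=1e-9)
        assert res.status == "empty-selection"
        with pytest.raises(ValueError):
            res.scores()
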