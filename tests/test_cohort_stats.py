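import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from cohmetrics import (
    PowerSpec,
    anova_dispatch,
    linear_fit,
    model_ladder,
    multinomial_fit,
    oneway_anova,
    pearson_chi_square,
    power_oneway,
    required_n,
    two_sample_t,
    vif,
    welch_anova,
    z_standardize,
)
from cohmetrics.cohort_stats import (
    DegenerateDataError,
    SeparationError,
    levene,
    multinomial_loglik,
    two_sample_t_data,
)


class TestZStandardize:
    def test_basic_column(self):
        z, rec = z_standardize(pd.DataFrame({"x": [1.0, 2.0, 3.0]}))
        assert np.allclose(z["x"], [-1, 0, 1])

    def test_idempotent_and_invertible(self):
        rng = np.random.default_rng(0)
        x = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        z, rec = z_standardize(x)
        z2, _ = z_standardize(z)
        assert np.allclose(z, z2, atol=1e-12)
        assert np.allclose(rec.inverse(z), x, atol=1e-12)

    def test_constant_column_named(self):
        with pytest.raises(DegenerateDataError, match="b"):
            z_standardize(pd.DataFrame({"a": [1.0, 2.0], "b": [5.0, 5.0]}))


class TestTwoSampleT:
    def test_identical_groups(self):
        t, df, p = two_sample_t(5.0, 1.0, 20, 5.0, 1.0, 20)
        assert t == 0.0
        assert p == pytest.approx(1.0)
        assert df == 38

    def test_summary_matches_raw_data_overload(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(0, 1, 25), rng.normal(0.5, 1.3, 30)
        t1, df1, p1 = two_sample_t_data(x, y)
        t2, df2, p2 = two_sample_t(
            x.mean(), x.std(ddof=1), 25, y.mean(), y.std(ddof=1), 30
        )
        assert (t1, df1, p1) == pytest.approx((t2, df2, p2))

    def test_degenerate_equal_constants(self):
        with pytest.raises(DegenerateDataError):
            two_sample_t(1.0, 0.0, 5, 1.0, 0.0, 5)

    def test_type_one_error_calibrated(self):
        """Rejection rate under the null stays within 1.5 points of 5%."""
        rng = np.random.default_rng(2024)
        reps, n = 5000, 50
        x = rng.normal(size=(reps, n))
        y = rng.normal(size=(reps, n))
        res = stats.ttest_ind(x, y, axis=1)
        rate = float((res.pvalue < 0.05).mean())
        assert 0.035 <= rate <= 0.065


class TestPearsonChiSquare:
    def test_matches_brute_force_cellwise(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            table = rng.integers(1, 40, size=(rng.integers(2, 4), rng.integers(2, 4)))
            chi2, df, p = pearson_chi_square(table)
            total = table.sum()
            expected = np.outer(table.sum(1), table.sum(0)) / total
            brute = ((table - expected) ** 2 / expected).sum()
            assert chi2 == pytest.approx(brute, abs=1e-10)
            assert df == (table.shape[0] - 1) * (table.shape[1] - 1)

    def test_proportional_table_gives_zero(self):
        assert pearson_chi_square([[10, 20], [5, 10]])[0] == pytest.approx(0.0)

    def test_zero_column_rejected(self):
        with pytest.raises(DegenerateDataError):
            pearson_chi_square([[0, 5], [0, 10]])

    def test_type_one_error_calibrated(self):
        """2x2 independence test under the null rejects at about 5%."""
        rng = np.random.default_rng(99)
        reps, n = 5000, 50
        a = rng.binomial(n, 0.5, size=reps)
        b = rng.binomial(n, 0.5, size=reps)
        # vectorized uncorrected Pearson on [[a, n-a], [b, n-b]]
        N = 2 * n
        col1 = a + b
        with np.errstate(invalid="ignore", divide="ignore"):
            chi2 = N * (a * (n - b) - (n - a) * b) ** 2 / (n * n * col1 * (N - col1))
        valid = (col1 > 0) & (col1 < N)
        pvals = stats.chi2.sf(chi2[valid], 1)
        rate = float((pvals < 0.05).mean())
        assert 0.035 <= rate <= 0.065


class TestAnova:
    def test_welch_agrees_with_classical_for_equal_variances(self):
        """With identical sample variances the two implementations coincide
        up to Welch's known small-sample denominator, exactly."""
        rng = np.random.default_rng(8)
        base = rng.normal(size=40)
        groups = [base, base + 0.3, base + 0.9]  # same sample variance by construction
        k, n = 3, 40
        f_c, _, _ = oneway_anova(groups)
        f_w, _, _ = welch_anova(groups)
        tmp = k * (1 - 1 / k) ** 2 / (n - 1)
        den = 1 + 2 * (k - 2) / (k**2 - 1) * tmp
        assert f_w == pytest.approx(f_c / den, abs=1e-10)

    def test_null_case_f_small(self):
        groups = [[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [1.0, 2.0, 3.0]]
        f, (df1, df2), p = oneway_anova(groups)
        assert f == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_levene_identical_spread_zero(self):
        g = [1.0, 2.0, 3.0]
        w, p = levene([g, [x + 5 for x in g], [x - 2 for x in g]])
        assert w == pytest.approx(0.0, abs=1e-12)

    def test_dispatcher_picks_welch_under_heteroscedasticity(self):
        rng = np.random.default_rng(9)
        groups = [rng.normal(0, 0.2, 50), rng.normal(0, 3.0, 50), rng.normal(0, 0.2, 50)]
        *_, which = anova_dispatch(groups)
        assert which == "welch"

    def test_dispatcher_picks_classical_under_homogeneity(self):
        rng = np.random.default_rng(10)
        groups = [rng.normal(m, 1.0, 50) for m in (0, 1, 2)]
        *_, which = anova_dispatch(groups)
        assert which == "anova"

    def test_welch_zero_variance_guarded(self):
        with pytest.raises(DegenerateDataError):
            welch_anova([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])


class TestLinearFit:
    def test_exact_line(self):
        x = np.arange(10.0)
        fit = linear_fit(2 * x, x)
        assert fit.slope == pytest.approx(2.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_predictor_rejected(self):
        with pytest.raises(DegenerateDataError):
            linear_fit([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])

    def test_null_slope_type_one_error(self):
        """With y independent of x the slope test rejects at about 5%."""
        rng = np.random.default_rng(17)
        reps, n = 2000, 50
        hits = 0
        x = rng.normal(size=(reps, n))
        y = rng.normal(size=(reps, n))
        # closed-form simple-regression t-test, vectorized over replicates
        xm = x - x.mean(1, keepdims=True)
        ym = y - y.mean(1, keepdims=True)
        b = (xm * ym).sum(1) / (xm**2).sum(1)
        resid = ym - b[:, None] * xm
        se = np.sqrt((resid**2).sum(1) / (n - 2) / (xm**2).sum(1))
        pvals = 2 * stats.t.sf(np.abs(b / se), n - 2)
        rate = float((pvals < 0.05).mean())
        assert 0.035 <= rate <= 0.065

    def test_slope_recovery_and_ci_coverage(self):
        """Effect-scale fixture: b = -0.35 with noise set for R^2 near 0.10."""
        rng = np.random.default_rng(21)
        b_true, n, reps = -0.35, 40, 300
        noise_sd = 1.05  # var explained .1225 over total 1.225
        covered = 0
        estimates = []
        for _ in range(reps):
            x = rng.normal(size=n)
            y = b_true * x + rng.normal(0, noise_sd, size=n)
            fit = linear_fit(y, x)
            estimates.append(fit.slope)
            if fit.ci[0] <= b_true <= fit.ci[1]:
                covered += 1
        assert np.mean(estimates) == pytest.approx(b_true, abs=0.05)
        assert 0.91 <= covered / reps <= 0.99

    def test_residual_normality_reported_as_bound(self):
        rng = np.random.default_rng(30)
        x = rng.normal(size=60)
        fit = linear_fit(1.5 * x + rng.normal(size=60), x)
        assert fit.normality_D > 0
        if fit.normality_p_is_bound:
            assert fit.normality_p == 0.2


class TestVif:
    def test_orthogonal_columns_unity(self):
        x = pd.DataFrame({"a": [1, -1, 1, -1], "b": [1, 1, -1, -1], "c": [1, -1, -1, 1]})
        assert np.allclose(vif(x), 1.0)

    def test_duplicated_column_signals_collinearity(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=20)
        x = pd.DataFrame({"a": a, "b": a})
        assert np.isinf(vif(x)).all()

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(12)
        x = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        x["c"] += 0.6 * x["a"]
        got = vif(x)
        for col in x.columns:
            others = x.drop(columns=col).to_numpy()
            design = np.column_stack([np.ones(len(x)), others])
            beta, *_ = np.linalg.lstsq(design, x[col].to_numpy(), rcond=None)
            resid = x[col].to_numpy() - design @ beta
            r2 = 1 - resid.var() / x[col].to_numpy().var()
            assert got[col] == pytest.approx(1 / (1 - r2), abs=1e-10)


def softmax_sample(rng, X, B):
    """Draw labels from the multinomial logit truth (reference level 0)."""
    eta = np.column_stack([np.zeros(len(X)), X @ B.T])
    p = np.exp(eta - eta.max(1, keepdims=True))
    p /= p.sum(1, keepdims=True)
    u = rng.random(len(X))
    return (u[:, None] > p.cumsum(1)).sum(1)


class TestMultinomialFit:
    def test_intercept_only_balanced_symmetry(self):
        y = ["HC"] * 20 + ["NAP_FTD"] * 20 + ["NAP_noFTD"] * 20
        fit = multinomial_fit(y, pd.DataFrame(index=range(60)))
        for o in fit.outcomes:
            assert o.coef["const"] == pytest.approx(0.0, abs=1e-8)
        assert fit.nagelkerke_r2 == pytest.approx(0.0, abs=1e-10)
        assert fit.lr_chi2 == pytest.approx(0.0, abs=1e-8)

    def test_agrees_with_independent_optimizer(self):
        """Newton MLE matches generic numerical maximization to 1e-6."""
        rng = np.random.default_rng(42)
        n, J = 200, 3
        X = rng.normal(size=(n, 2))
        B = np.array([[0.2, 0.8, -0.4], [-0.3, -0.5, 0.7]])  # (J-1) x (1+p)
        Xc = np.column_stack([np.ones(n), X])
        y = softmax_sample(rng, Xc, B)
        labels = np.array(["HC", "A", "B"])[y]
        fit = multinomial_fit(labels, pd.DataFrame(X, columns=["x1", "x2"]), reference="HC")

        res = optimize.minimize(
            lambda b: -multinomial_loglik(b, Xc, y, J),
            x0=np.zeros(2 * 3),
            method="BFGS",
            options={"gtol": 1e-10, "maxiter": 2000},
        )
        assert -res.fun == pytest.approx(fit.loglik, abs=1e-6)
        oracle = res.x.reshape(J - 1, 3)
        ours = np.array([fit.outcome(lv).coef.to_numpy() for lv in ("A", "B")])
        assert np.allclose(ours, oracle, atol=1e-5)

    def test_parameter_recovery_at_n600(self):
        """Estimates fall within 2 SE of the generating coefficients."""
        rng = np.random.default_rng(0)
        n, J = 600, 3
        X = rng.normal(size=(n, 4))
        B = np.array(
            [[0.1, 0.8, -0.5, 0.3, 0.0], [-0.2, -0.4, 0.6, 0.0, 0.5]]
        )
        Xc = np.column_stack([np.ones(n), X])
        y = softmax_sample(rng, Xc, B)
        labels = np.array(["HC", "A", "B"])[y]
        fit = multinomial_fit(
            labels, pd.DataFrame(X, columns=[f"x{i}" for i in range(4)]), reference="HC"
        )
        within = 0
        total = 0
        for j, lv in enumerate(("A", "B")):
            o = fit.outcome(lv)
            for k in range(5):
                total += 1
                if abs(o.coef.iloc[k] - B[j, k]) <= 2 * o.se.iloc[k]:
                    within += 1
        assert within / total >= 0.9

    def test_odds_ratios_consistent_with_coefficients(self, study_features):
        z, _ = z_standardize(study_features[["acm"]])
        fit = multinomial_fit(study_features["group"], z)
        for o in fit.outcomes:
            assert np.allclose(o.odds_ratio, np.exp(o.coef))
            assert (o.or_ci_low <= o.odds_ratio).all()
            assert (o.odds_ratio <= o.or_ci_high).all()

    def test_perfect_separation_diagnosed(self):
        x = pd.DataFrame({"x": [-3.0, -2.0, -1.0, 1.0, 2.0, 3.0, 5.0, 6.0, 7.0]})
        y = ["HC"] * 3 + ["A"] * 3 + ["B"] * 3
        with pytest.raises(SeparationError):
            multinomial_fit(y, x)

    def test_reference_must_be_observed(self):
        with pytest.raises(ValueError):
            multinomial_fit(["A", "B"], pd.DataFrame({"x": [1.0, 2.0]}), reference="HC")


class TestModelLadder:
    def test_nagelkerke_non_decreasing_and_bounded(self, study_features):
        fits, comparison = model_ladder(study_features)
        r2 = [f.nagelkerke_r2 for f in fits]
        assert all(0.0 <= v <= 1.0 for v in r2)
        assert r2[0] <= r2[1] <= r2[2] + 1e-9

    def test_models_fit_on_identical_rows(self, study_features):
        fits, _ = model_ladder(study_features)
        ns = [int(f.classification["n"].sum()) for f in fits]
        assert len(set(ns)) == 1

    def test_interaction_is_product_of_z_scores(self, study_features):
        fits, _ = model_ladder(study_features)
        assert "acm_x_repetition" in fits[1].predictors


class TestPower:
    def test_zero_effect_gives_alpha(self):
        for alpha in (0.01, 0.05, 0.1):
            spec = PowerSpec(k=3, n_total=60, effect_f=0.0, alpha=alpha)
            assert power_oneway(spec) == pytest.approx(alpha)

    def test_monotone_in_n_and_f(self):
        grid_n = [30, 60, 120, 240]
        grid_f = [0.1, 0.25, 0.4, 0.6]
        for f in grid_f:
            powers = [power_oneway(PowerSpec(3, n, f)) for n in grid_n]
            assert all(a < b for a, b in zip(powers, powers[1:]))
        for n in grid_n:
            powers = [power_oneway(PowerSpec(3, n, f)) for f in grid_f]
            assert all(a < b for a, b in zip(powers, powers[1:]))

    def test_required_n_is_minimal_on_grid(self):
        n = required_n(3, 0.325, alpha=0.05, target_power=0.8)
        assert power_oneway(PowerSpec(3, n, 0.325)) >= 0.8
        assert power_oneway(PowerSpec(3, n - 3, 0.325)) < 0.8

    def test_zero_effect_impossible_design(self):
        with pytest.raises(ValueError):
            required_n(3, 0.0, target_power=0.8)
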