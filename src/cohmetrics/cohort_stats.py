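"""Cohort-level statistics: group tests, regressions, diagnostics, power.

Conventions, chosen to match standard clinical-statistics software output:

* Pearson chi-square without continuity correction.
* Student's pooled-variance t for two-group comparisons (Welch optional).
* One-way ANOVA with a Levene homogeneity gate at alpha = .05 selecting
  Welch's ANOVA when variances are heterogeneous.
* OLS for linear regression, with a Lilliefors (Kolmogorov-Smirnov with
  estimated parameters) residual-normality check whose p is reported as a
  ">= .2" bound beyond the table range.
* Multinomial logistic regression by Newton-type maximum likelihood with the
  healthy-control group as reference; observed-information standard errors,
  Wald odds-ratio confidence intervals exp(b +/- 1.96 SE), Nagelkerke pseudo
  R-squared, likelihood-ratio test against the intercept-only model, and an
  argmax classification table.
* Noncentral-F power for the one-way fixed-effects design with
  lambda = f^2 * N_total and df2 = N - k (the G*Power omnibus convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.tools.sm_exceptions import PerfectSeparationError

log = logging.getLogger(__name__)

GROUPS = ("HC", "NAP_FTD", "NAP_noFTD")


class DegenerateDataError(ValueError):
    pass


class SeparationError(RuntimeError):
    """Perfect (quasi-)separation or non-convergence in multinomial fitting."""


# ---------------------------------------------------------------------------
# scaling

@dataclass
class ScalingRecord:
    means: pd.Series
    sds: pd.Series

    def inverse(self, z: pd.DataFrame) -> pd.DataFrame:
        return z * self.sds + self.means


def z_standardize(x: pd.DataFrame) -> tuple[pd.DataFrame, ScalingRecord]:
    """Column-wise z-scores (ddof=1) over non-missing rows; record retained."""
    x = pd.DataFrame(x).astype(float)
    sds = x.std(ddof=1)
    bad = sds[(sds == 0) | sds.isna()].index.tolist()
    if bad:
        raise DegenerateDataError(f"constant column(s): {bad}")
    means = x.mean()
    return (x - means) / sds, ScalingRecord(means=means, sds=sds)


# ---------------------------------------------------------------------------
# simple group tests

def two_sample_t(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int,
    equal_var: bool = True,
) -> tuple[float, float, float]:
    """Pooled-variance Student t from summary statistics -> (t, df, p)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("SDs must be nonnegative")
    if sd1 == 0 and sd2 == 0 and mean1 == mean2:
        raise DegenerateDataError("both groups constant and equal: t undefined")
    res = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=equal_var)
    if equal_var:
        df = n1 + n2 - 2
    else:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def two_sample_t_data(x: Sequence[float], y: Sequence[float], equal_var: bool = True):
    """Raw-data overload of :func:`two_sample_t`."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    return two_sample_t(
        x.mean(), x.std(ddof=1), len(x), y.mean(), y.std(ddof=1), len(y), equal_var
    )


def pearson_chi_square(table) -> tuple[float, int, float]:
    """Uncorrected Pearson chi-square on a contingency table -> (chi2, df, p)."""
    table = np.asarray(table, dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be nonnegative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise DegenerateDataError("contingency table has a zero row or column")
    chi2, p, df, expected = stats.chi2_contingency(table, correction=False)
    if (expected <= 0).any():
        raise DegenerateDataError("expected count <= 0")
    return float(chi2), int(df), float(p)


def oneway_anova(groups: Sequence[Sequence[float]]) -> tuple[float, tuple[int, int], float]:
    """Classical one-way fixed-effects F -> (F, (df1, df2), p)."""
    groups = [np.asarray(g, float) for g in groups]
    _check_groups(groups)
    f, p = stats.f_oneway(*groups)
    k = len(groups)
    n = sum(len(g) for g in groups)
    return float(f), (k - 1, n - k), float(p)


def welch_anova(groups: Sequence[Sequence[float]]) -> tuple[float, tuple[float, float], float]:
    """Welch's heteroscedastic F with Welch-Satterthwaite df -> (F, (df1, df2), p)."""
    groups = [np.asarray(g, float) for g in groups]
    _check_groups(groups)
    if any(g.var(ddof=1) == 0 for g in groups):
        raise DegenerateDataError("a group has zero variance; Welch weights undefined")
    k = len(groups)
    n = np.array([len(g) for g in groups], float)
    m = np.array([g.mean() for g in groups])
    v = np.array([g.var(ddof=1) for g in groups])
    w = n / v
    mw = (w * m).sum() / w.sum()
    num = ((w * (m - mw) ** 2).sum()) / (k - 1)
    tmp = ((1 - w / w.sum()) ** 2 / (n - 1)).sum()
    den = 1 + 2 * (k - 2) / (k**2 - 1) * tmp
    f = num / den
    df1 = k - 1
    df2 = (k**2 - 1) / (3 * tmp)
    p = stats.f.sf(f, df1, df2)
    return float(f), (float(df1), float(df2)), float(p)


def levene(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Levene's W on absolute deviations from group means -> (W, p)."""
    groups = [np.asarray(g, float) for g in groups]
    _check_groups(groups)
    w, p = stats.levene(*groups, center="mean")
    return float(w), float(p)


def anova_dispatch(groups, alpha: float = 0.05):
    """Classical or Welch ANOVA depending on Levene homogeneity at *alpha*.

    Returns (F, df, p, which) with which in {"anova", "welch"}; choice logged.
    """
    w, p_lev = levene(groups)
    if p_lev < alpha:
        log.info("Levene p=%.4f < %.2f: variances heterogeneous, using Welch", p_lev, alpha)
        f, df, p = welch_anova(groups)
        return f, df, p, "welch"
    log.info("Levene p=%.4f >= %.2f: using classical ANOVA", p_lev, alpha)
    f, df, p = oneway_anova(groups)
    return f, df, p, "anova"


def _check_groups(groups) -> None:
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs n >= 2")


# ---------------------------------------------------------------------------
# linear regression

@dataclass
class LinearFit:
    slope: float
    se: float
    ci: tuple[float, float]
    p: float
    intercept: float
    r_squared: float
    f_stat: float
    f_p: float
    residuals: np.ndarray
    normality_D: float
    normality_p: float
    normality_p_is_bound: bool

    def summary(self) -> dict:
        p_norm = f">= {self.normality_p:.2g}" if self.normality_p_is_bound else f"{self.normality_p:.3g}"
        return {
            "b": self.slope,
            "se": self.se,
            "ci95": list(self.ci),
            "p": self.p,
            "r_squared": self.r_squared,
            "F": self.f_stat,
            "F_p": self.f_p,
            "residual_normality_D": self.normality_D,
            "residual_normality_p": p_norm,
        }


def linear_fit(y: Sequence[float], x: Sequence[float]) -> LinearFit:
    """Simple OLS of a clinical rating on one predictor, with diagnostics."""
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    if len(y) != len(x):
        raise ValueError("y and x differ in length")
    if len(y) < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0:
        raise DegenerateDataError("constant predictor")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int(alpha=0.05)[1]
    resid = np.asarray(fit.resid)
    d, p_norm = lilliefors(resid, dist="norm")
    # the Lilliefors table tops out at .2: beyond it only the bound is known
    bound = p_norm >= 0.2
    return LinearFit(
        slope=float(fit.params[1]),
        se=float(fit.bse[1]),
        ci=(float(ci[0]), float(ci[1])),
        p=float(fit.pvalues[1]),
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        f_stat=float(fit.fvalue),
        f_p=float(fit.f_pvalue),
        residuals=resid,
        normality_D=float(d),
        normality_p=0.2 if bound else float(p_norm),
        normality_p_is_bound=bound,
    )


# ---------------------------------------------------------------------------
# multinomial logistic regression

@dataclass
class OutcomeEstimates:
    """Estimates for one non-reference outcome level."""

    outcome: str
    coef: pd.Series
    se: pd.Series
    p: pd.Series
    odds_ratio: pd.Series
    or_ci_low: pd.Series
    or_ci_high: pd.Series


@dataclass
class MultinomialFit:
    reference: str
    outcomes: list[OutcomeEstimates]
    loglik: float
    loglik_null: float
    n_params: int
    aic: float
    nagelkerke_r2: float
    lr_chi2: float
    lr_df: int
    lr_p: float
    classification: pd.DataFrame  # rows observed group, column pct_correct
    converged: bool
    predictors: list[str] = field(default_factory=list)

    def outcome(self, name: str) -> OutcomeEstimates:
        for o in self.outcomes:
            if o.outcome == name:
                return o
        raise KeyError(name)


def multinomial_loglik(beta: np.ndarray, X: np.ndarray, y_codes: np.ndarray, J: int) -> float:
    """Multinomial log-likelihood with reference level coded 0.

    *beta* is flat with shape ((J-1)*p,); linear predictor of the reference
    level is 0.  Kept public: it doubles as the target for the independent
    optimizer cross-check in the test-suite.
    """
    n, p = X.shape
    B = beta.reshape(J - 1, p).T  # p x (J-1)
    eta = np.column_stack([np.zeros(n), X @ B])
    eta -= eta.max(axis=1, keepdims=True)
    logden = np.log(np.exp(eta).sum(axis=1))
    return float((eta[np.arange(n), y_codes] - logden).sum())


def multinomial_fit(
    outcome: Sequence[str],
    predictors: pd.DataFrame,
    reference: str = "HC",
) -> MultinomialFit:
    """Newton-type ML multinomial logit with *reference* as baseline level."""
    y = pd.Series(list(outcome)).astype(str)
    levels = [reference] + sorted(set(y) - {reference})
    if reference not in set(y):
        raise ValueError(f"reference level {reference!r} not observed")
    if len(levels) < 2:
        raise ValueError("outcome needs >= 2 observed levels")
    X = pd.DataFrame(predictors).astype(float).reset_index(drop=True)
    if X.isna().any().any():
        raise ValueError("missing values in predictors; apply listwise deletion first")
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc.to_numpy()) < Xc.shape[1]:
        raise DegenerateDataError("design matrix not full rank")
    codes = y.map({lv: i for i, lv in enumerate(levels)}).to_numpy()

    model = sm.MNLogit(codes, Xc.to_numpy())
    try:
        fit = model.fit(method="newton", maxiter=200, disp=False)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise SeparationError(f"multinomial fit failed: {exc}") from exc
    if not np.all(np.isfinite(fit.params)):
        # Newton can overshoot on ill-conditioned designs; retry with a
        # gradient method before declaring separation
        fit = model.fit(method="bfgs", maxiter=1000, disp=False, gtol=1e-8)
    converged = bool(fit.mle_retvals.get("converged", False))
    try:
        bse_ok = np.all(np.isfinite(fit.bse))
    except ValueError:  # Hessian inversion failed: no covariance available
        bse_ok = False
    if not converged or not bse_ok or np.abs(fit.params).max() > 30:
        raise SeparationError(
            "multinomial fit did not converge cleanly (possible perfect separation); "
            f"max|b|={np.abs(fit.params).max():.3g}, converged={converged}"
        )

    names = ["const"] + list(X.columns)
    J = len(levels)
    n = len(y)
    outcomes = []
    params = np.asarray(fit.params)  # (p, J-1)
    bse = np.asarray(fit.bse)
    pvals = np.asarray(fit.pvalues)
    for j in range(1, J):
        b = pd.Series(params[:, j - 1], index=names)
        se = pd.Series(bse[:, j - 1], index=names)
        p = pd.Series(pvals[:, j - 1], index=names)
        outcomes.append(
            OutcomeEstimates(
                outcome=levels[j],
                coef=b,
                se=se,
                p=p,
                odds_ratio=np.exp(b),
                or_ci_low=np.exp(b - 1.96 * se),
                or_ci_high=np.exp(b + 1.96 * se),
            )
        )

    ll1 = float(fit.llf)
    # intercept-only log-likelihood in closed form: multinomial proportions
    counts = np.bincount(codes, minlength=J)
    ll0 = float(sum(c * np.log(c / n) for c in counts if c > 0))
    k_params = Xc.shape[1] * (J - 1)
    lr_df = (Xc.shape[1] - 1) * (J - 1)
    lr = 2 * (ll1 - ll0)
    r2_cs = 1 - np.exp(2 * (ll0 - ll1) / n)
    r2_max = 1 - np.exp(2 * ll0 / n)
    nagelkerke = float(r2_cs / r2_max) if r2_max > 0 else 0.0

    pred = np.asarray(fit.predict()).argmax(axis=1)
    rows = []
    for j, lv in enumerate(levels):
        mask = codes == j
        pct = 100.0 * (pred[mask] == j).mean() if mask.any() else np.nan
        rows.append({"group": lv, "n": int(mask.sum()), "pct_correct": pct})
    classification = pd.DataFrame(rows).set_index("group")

    return MultinomialFit(
        reference=reference,
        outcomes=outcomes,
        loglik=ll1,
        loglik_null=ll0,
        n_params=k_params,
        aic=2 * k_params - 2 * ll1,
        nagelkerke_r2=nagelkerke,
        lr_chi2=float(lr),
        lr_df=lr_df,
        lr_p=float(stats.chi2.sf(lr, lr_df)) if lr_df > 0 else 1.0,
        classification=classification,
        converged=converged,
        predictors=list(X.columns),
    )


def model_ladder(
    features: pd.DataFrame,
    reference: str = "HC",
    extra_predictors: Sequence[str] = ("neologism_pct", "ambiguous_referent_rate"),
    selected_categories: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> tuple[list[MultinomialFit], pd.DataFrame]:
    """Fit the three-step predictor ladder on identical rows.

    Model 1: coherence metric (ACM) only.  Model 2: ACM, repetitions, and
    their interaction (product of the z-scored columns).  Model 3 adds the
    comprehensibility features and the dictionary categories that pass the
    significant-group-difference gate.  All predictors are z-scored over the
    analysed rows; rows with any missing value among the Model-3 predictors
    are dropped listwise (count logged) so the three models see the same rows.
    """
    from .aux_features import select_significant_categories

    if selected_categories is None:
        selected_categories = select_significant_categories(features, alpha=alpha)
    base = ["acm", "repetition_rate"]
    extras = [c for c in extra_predictors if c in features.columns]
    all_cols = base + extras + list(selected_categories)
    needed = ["group"] + all_cols
    data = features[needed].dropna()
    dropped = len(features) - len(data)
    if dropped:
        log.info("listwise deletion removed %d row(s) with missing features", dropped)
    z, _ = z_standardize(data[all_cols])
    z["acm_x_repetition"] = z["acm"] * z["repetition_rate"]
    y = data["group"]

    m1 = multinomial_fit(y, z[["acm"]], reference)
    m2 = multinomial_fit(y, z[["acm", "repetition_rate", "acm_x_repetition"]], reference)
    m3_cols = ["acm", "repetition_rate"] + extras + list(selected_categories)
    m3 = multinomial_fit(y, z[m3_cols], reference)
    fits = [m1, m2, m3]
    comparison = pd.DataFrame(
        {
            "model": ["Model 1", "Model 2", "Model 3"],
            "AIC": [f.aic for f in fits],
            "nagelkerke_r2": [f.nagelkerke_r2 for f in fits],
            "lr_chi2": [f.lr_chi2 for f in fits],
            "lr_df": [f.lr_df for f in fits],
            "lr_p": [f.lr_p for f in fits],
        }
    )
    comparison["best_aic"] = comparison["AIC"] == comparison["AIC"].min()
    return fits, comparison


# ---------------------------------------------------------------------------
# collinearity & power

def vif(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factor 1/(1-R2_j) per column."""
    X = pd.DataFrame(X).astype(float)
    if X.shape[1] < 2:
        raise ValueError("VIF needs >= 2 columns")
    out = {}
    for col in X.columns:
        others = sm.add_constant(X.drop(columns=col))
        r2 = sm.OLS(X[col], others).fit().rsquared
        out[col] = np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


@dataclass
class PowerSpec:
    k: int
    n_total: int
    effect_f: float
    alpha: float = 0.05
    design: str = "oneway_anova"

    def __post_init__(self) -> None:
        if self.design != "oneway_anova":
            raise ValueError(f"unsupported design {self.design!r}")
        if self.k < 2:
            raise ValueError("k >= 2 required")
        if self.n_total <= self.k:
            raise ValueError("N must exceed k")
        if self.effect_f < 0:
            raise ValueError("effect size f must be >= 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha in (0,1) required")


def power_oneway(spec: PowerSpec) -> float:
    """P(F' > F_crit) with F' noncentral F(k-1, N-k, lambda = f^2 N)."""
    df1 = spec.k - 1
    df2 = spec.n_total - spec.k
    lam = spec.effect_f**2 * spec.n_total
    f_crit = stats.f.ppf(1 - spec.alpha, df1, df2)
    if lam == 0:
        return float(spec.alpha)
    return float(stats.ncf.sf(f_crit, df1, df2, lam))


def required_n(
    k: int, effect_f: float, alpha: float = 0.05, target_power: float = 0.8,
    equal_groups: bool = True,
) -> int:
    """Smallest total N (a multiple of k for equal groups) with power >= target."""
    if effect_f <= 0 and target_power > alpha:
        raise ValueError("f = 0 cannot reach power above alpha: impossible design")
    step = k if equal_groups else 1
    n = k + step  # smallest N with df2 > 0 on the grid
    while n < 10**6:
        if power_oneway(PowerSpec(k=k, n_total=n, effect_f=effect_f, alpha=alpha)) >= target_power:
            return n
        n += step
    raise RuntimeError("no N below 1e6 reaches the target power")
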