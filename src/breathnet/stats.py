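"""Cohort-level statistics for the network-similarity analysis.

Covers the downstream inferential layer: one-way repeated-measures ANOVA
on network-similarity columns with Mauchly's sphericity test and the
Greenhouse-Geisser correction, partial eta squared as effect size,
chi-square comparison of symptom occurrence against the control arm,
McNemar's paired test for headache, logistic (binomial) regressions of
total TE or SpO2/FiO2 ratio on symptom occurrence with VIF / AIC / BIC /
McFadden R^2 / AUC, pairwise Pearson and Kendall tau-B correlation
matrices, and the SpO2/FiO2 summaries.

Model fitting is delegated to statsmodels / pingouin / scikit-learn; this
module fixes the conventions (which sums of squares, which correction,
which effect size) so results are reproducible and comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_auc_score
from statsmodels.stats.outliers_influence import variance_inflation_factor
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "AnovaResult", "ChiSquareResult", "RegressionResult",
    "rm_anova_gg", "chi_square_vs_control", "mcnemar_test",
    "logistic_symptom_regression", "correlation_matrix",
    "sf_ratio", "spo2_fio2_regression",
]


@dataclass
class AnovaResult:
    """One-way repeated-measures ANOVA with sphericity handling."""

    F: float
    df_effect: float
    df_error: float
    p: float
    eta2p: float           # SS_effect / (SS_effect + SS_error)
    mauchly_w: float
    mauchly_p: float
    gg_epsilon: float
    corrected: bool        # True when GG-corrected dfs produced ``p``


@dataclass
class ChiSquareResult:
    chi2: float
    df: int
    p: float
    exact_p: float | None = None  # exact binomial p (McNemar, few discordant)
    note: str = ""


@dataclass
class RegressionResult:
    """Maximum-likelihood logistic fit with fit-quality diagnostics."""

    predictors: list[str]
    coefficients: dict[str, float]
    odds_ratios: dict[str, float]
    p_values: dict[str, float]
    overall_p: float       # likelihood-ratio test vs. the null model
    score_p: float         # Rao score test of the global null; unlike the
                           # LR test it stays calibrated at very small n
    auc: float
    r2_mcfadden: float
    aic: float
    bic: float
    vif: dict[str, float]


def rm_anova_gg(values, gg_threshold: float = 0.05) -> AnovaResult:
    """One-way RM-ANOVA (participants x levels) with GG correction.

    Sums of squares are the classical within-subject decomposition;
    partial eta squared is ``SS_effect / (SS_effect + SS_error)``.
    Mauchly's test and the Greenhouse-Geisser epsilon come from pingouin;
    degrees of freedom are deflated by epsilon only when Mauchly's p
    falls below ``gg_threshold`` (with two levels sphericity holds
    trivially and epsilon is exactly 1).
    """
    X = values.to_numpy(dtype=float) if isinstance(values, pd.DataFrame) \
        else np.asarray(values, dtype=float)
    if X.ndim != 2:
        raise ValueError("values must be a participants x levels matrix")
    n, k = X.shape
    if k < 2:
        raise ValueError("need at least 2 within-subject levels")
    if n < 3:
        raise ValueError("need at least 3 participants")
    if not np.isfinite(X).all():
        raise ValueError("missing or non-finite cells: complete cases required")

    grand = X.mean()
    ss_effect = n * ((X.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((X.mean(axis=1) - grand) ** 2).sum()
    ss_total = ((X - grand) ** 2).sum()
    ss_error = ss_total - ss_effect - ss_subj
    df_effect = float(k - 1)
    df_error = float((n - 1) * (k - 1))
    ms_effect = ss_effect / df_effect
    ms_error = ss_error / df_error
    # guard degenerate decompositions (identical columns leave only
    # floating-point dust in the sums of squares)
    tiny = 1e-12 * max(ss_total, 1.0)
    if ss_effect <= tiny:
        F = 0.0
        eta2p = 0.0
    else:
        F = ms_effect / ms_error if ms_error > 0 else np.inf
        eta2p = ss_effect / (ss_effect + ss_error)

    if k == 2:
        w, w_p, eps = 1.0, 1.0, 1.0
    else:
        df_wide = pd.DataFrame(X)
        with np.errstate(divide="ignore", invalid="ignore"):
            spher = pg.sphericity(df_wide)
            w, w_p = float(spher.W), float(spher.pval)
            eps = float(pg.epsilon(df_wide, correction="gg"))
        if not (np.isfinite(w) and np.isfinite(w_p)):
            w, w_p, eps = 1.0, 1.0, 1.0  # degenerate covariance

    corrected = bool(w_p < gg_threshold)
    d1, d2 = (df_effect * eps, df_error * eps) if corrected else (df_effect, df_error)
    p = float(stats.f.sf(F, d1, d2)) if F > 0 else 1.0
    return AnovaResult(F=float(F), df_effect=d1, df_error=d2, p=p,
                       eta2p=float(eta2p), mauchly_w=w, mauchly_p=w_p,
                       gg_epsilon=eps, corrected=corrected)


def chi_square_vs_control(control_yes: int, test_yes: int, n: int) -> ChiSquareResult:
    """Goodness-of-fit of a test arm's yes/no counts to the control rate.

    The control arm fixes the expected proportion ``control_yes / n``;
    the test arm's observed (yes, no) counts are compared with
    ``chi2 = sum (O - E)^2 / E`` on 1 degree of freedom.
    """
    if not (0 <= control_yes <= n and 0 <= test_yes <= n):
        raise ValueError("counts must lie in [0, n]")
    if control_yes in (0, n):
        raise ValueError("control proportion of 0 or 1 gives a zero expected "
                         "cell; use an exact test instead")
    p0 = control_yes / n
    observed = np.array([test_yes, n - test_yes], dtype=float)
    expected = np.array([n * p0, n * (1 - p0)])
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return ChiSquareResult(chi2=chi2, df=1, p=float(stats.chi2.sf(chi2, 1)))


def mcnemar_test(paired_flags) -> ChiSquareResult:
    """McNemar's test for paired yes/no outcomes (e.g. headache per arm).

    ``paired_flags`` is a sequence of (condition_a, condition_b) booleans
    per participant.  With discordant counts b (yes->no) and c (no->yes),
    the asymptotic statistic is ``(b - c)^2 / (b + c)`` on 1 df; the exact
    two-sided binomial p is reported in addition whenever ``b + c < 25``.
    No discordance yields chi2 = 0, p = 1, flagged.
    """
    flags = [(bool(a), bool(b)) for a, b in paired_flags]
    b = sum(1 for a, bb in flags if a and not bb)
    c = sum(1 for a, bb in flags if not a and bb)
    if b + c == 0:
        return ChiSquareResult(chi2=0.0, df=1, p=1.0, note="no discordance")
    chi2 = (b - c) ** 2 / (b + c)
    p = float(stats.chi2.sf(chi2, 1))
    exact_p = None
    if b + c < 25:
        exact_p = float(min(1.0, 2.0 * stats.binom.cdf(min(b, c), b + c, 0.5)))
    return ChiSquareResult(chi2=float(chi2), df=1, p=p, exact_p=exact_p)


def logistic_symptom_regression(predictors, outcome,
                                names: list[str] | None = None) -> RegressionResult:
    """Binomial (logistic) regression of a binary outcome on predictors.

    Reports per-predictor odds ratios and Wald p-values, the overall
    likelihood-ratio p, AUC of the fitted probabilities, McFadden's
    R^2 = 1 - ll_model / ll_null, AIC/BIC, and VIFs over the predictor
    set.  Perfect separation is detected and raised rather than returning
    a silently diverged fit.
    """
    if isinstance(predictors, pd.DataFrame):
        names = list(predictors.columns)
        X = predictors.to_numpy(dtype=float)
    else:
        X = np.asarray(predictors, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = names or [f"x{i + 1}" for i in range(X.shape[1])]
    y = np.asarray(outcome, dtype=float)
    n = y.size
    if n < 10:
        raise ValueError("need at least 10 observations")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")

    # Zero-variance predictors carry no information and would make the
    # design singular: they enter the report with OR 1 and p 1, and the
    # model is fitted on the informative columns (possibly the null model).
    live = [i for i in range(X.shape[1]) if np.ptp(X[:, i]) > 0]
    if len(live) < X.shape[1]:
        dead = [names[i] for i in range(X.shape[1]) if i not in live]
        sub = logistic_symptom_regression(X[:, live], y,
                                          [names[i] for i in live]) \
            if live else _null_logistic(y, [])
        for nm in dead:
            sub.predictors.append(nm)
            sub.coefficients[nm] = 0.0
            sub.odds_ratios[nm] = 1.0
            sub.p_values[nm] = 1.0
            sub.vif[nm] = 1.0
        return sub

    Xc = sm.add_constant(X, has_constant="add")
    import warnings as _warnings

    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning
    with _warnings.catch_warnings(record=True) as caught:
        _warnings.simplefilter("always")
        try:
            fit = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        except PerfectSeparationError as exc:
            raise ValueError(f"perfect separation detected: {exc}") from exc
    if any(issubclass(w.category, PerfectSeparationWarning) for w in caught):
        raise ValueError("perfect separation detected: parameters not identified")
    if not np.isfinite(fit.params).all() or np.abs(fit.params).max() > 50:
        raise ValueError("perfect or quasi-perfect separation: "
                         "coefficients diverged")

    k = X.shape[1]
    coef = dict(zip(names, fit.params[1:]))
    lr_stat = 2.0 * (fit.llf - fit.llnull)
    overall_p = float(stats.chi2.sf(max(lr_stat, 0.0), k))
    # Rao score test of the global null, evaluated at the intercept-only
    # fit: U = Xc'(y - ybar), V = ybar(1-ybar) Xc'Xc with Xc centred.
    ybar = y.mean()
    Xcen = X - X.mean(axis=0)
    U = Xcen.T @ (y - ybar)
    V = ybar * (1.0 - ybar) * (Xcen.T @ Xcen)
    score_stat = float(U @ np.linalg.solve(V, U))
    score_p = float(stats.chi2.sf(score_stat, k))
    probs = fit.predict(Xc)
    if k == 1:
        vif = {names[0]: 1.0}
    else:
        vif = {names[i]: float(variance_inflation_factor(Xc, i + 1))
               for i in range(k)}
    r2 = 1.0 - fit.llf / fit.llnull if fit.llnull != 0 else 0.0
    return RegressionResult(
        predictors=names,
        coefficients={nm: float(v) for nm, v in coef.items()},
        odds_ratios={nm: float(np.exp(v)) for nm, v in coef.items()},
        p_values=dict(zip(names, (float(v) for v in fit.pvalues[1:]))),
        overall_p=overall_p,
        score_p=score_p,
        auc=float(roc_auc_score(y, probs)),
        r2_mcfadden=float(max(r2, 0.0)),
        aic=float(fit.aic),
        bic=float(fit.bic),
        vif=vif,
    )


def _null_logistic(y: np.ndarray, names: list[str]) -> RegressionResult:
    """Intercept-only fit: McFadden R^2 = 0, AUC = 0.5 by construction."""
    fit = sm.Logit(y, np.ones((y.size, 1))).fit(disp=0)
    return RegressionResult(predictors=list(names), coefficients={},
                            odds_ratios={}, p_values={}, overall_p=1.0,
                            score_p=1.0, auc=0.5, r2_mcfadden=0.0,
                            aic=float(fit.aic), bic=float(fit.bic), vif={})


def correlation_matrix(values: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Pairwise Pearson r and tie-corrected Kendall tau-B with p-values.

    Returns full symmetric matrices; read the lower triangle for the
    conventional table layout.  Zero-variance columns are rejected.
    """
    df = pd.DataFrame(values)
    if df.shape[0] < 3:
        raise ValueError("need at least 3 complete cases")
    if df.isna().any().any():
        raise ValueError("missing values: complete cases required")
    cols = list(df.columns)
    for c in cols:
        if df[c].std(ddof=0) == 0:
            raise ValueError(f"column {c!r} has zero variance; "
                             "correlation undefined")
    k = len(cols)
    out = {key: pd.DataFrame(np.eye(k), index=cols, columns=cols)
           for key in ("pearson_r", "pearson_p", "kendall_tau", "kendall_p")}
    out["pearson_p"][:] = 0.0
    out["kendall_p"][:] = 0.0
    for i in range(k):
        for j in range(i + 1, k):
            x, y = df[cols[i]], df[cols[j]]
            r, rp = stats.pearsonr(x, y)
            tau, tp = stats.kendalltau(x, y, variant="b")
            for key, val in (("pearson_r", r), ("pearson_p", rp),
                             ("kendall_tau", tau), ("kendall_p", tp)):
                out[key].iloc[i, j] = out[key].iloc[j, i] = float(val)
    return out


def sf_ratio(spo2_percent: float, fio2_fraction: float) -> float:
    """SpO2 (%) over FiO2 (fraction): desaturation per unit hypoxic stimulus."""
    if fio2_fraction <= 0:
        raise ValueError("FiO2 must be a positive fraction")
    return float(spo2_percent / fio2_fraction)


@dataclass
class LineFit:
    slope: float
    intercept: float
    r: float
    sy_x: float  # residual SD with n - 2 denominator


def spo2_fio2_regression(fio2_percent, spo2_percent) -> LineFit:
    """OLS of spot SpO2 on FiO2 (both in %), with Pearson r and Sy.x."""
    x = np.asarray(fio2_percent, dtype=float)
    y = np.asarray(spo2_percent, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 points")
    if np.ptp(x) == 0:
        raise ValueError("FiO2 values are constant; slope undefined")
    res = stats.linregress(x, y)
    resid = y - (res.slope * x + res.intercept)
    dof = max(x.size - 2, 1)
    return LineFit(slope=float(res.slope), intercept=float(res.intercept),
                   r=float(res.rvalue),
                   sy_x=float(np.sqrt((resid ** 2).sum() / dof)))
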