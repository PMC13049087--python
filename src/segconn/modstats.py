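"""Outcome-level statistics: brain–behavior regressions and age moderation.

The behavioral outcome is each subject's logistic slope (responsiveness to
situational changes). Neural predictors (cluster NAI values or directed
connectivity) enter simple OLS regressions and, with age as moderator, a
moderation model Y ~ b0 + b1 X + b2 W + b3 X*W with heteroskedasticity-
consistent (HC3) inference, Johnson–Neyman regions of significance, simple
slopes at mean +/- 1 SD of age, Cook's distance screening, and
Benjamini–Hochberg correction within predefined families.

Predictors and the moderator enter uncentered, so Johnson–Neyman boundaries
and conditional effects are reported on the raw age axis (years).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.stattools import durbin_watson

__all__ = ["SimpleRegressionResult", "ModerationResult", "JNOutput",
           "FDRFamily", "simple_regression", "moderation_fit",
           "johnson_neyman", "bh_adjust", "cooks_distance", "simple_slopes",
           "AgeModeration"]


@dataclass(frozen=True)
class SimpleRegressionResult:
    r2: float
    f: float
    p: float
    durbin_watson: float
    coef: float
    intercept: float
    n: int


def simple_regression(predictor, outcome) -> SimpleRegressionResult:
    """OLS of the behavioral slope on one neural predictor.

    Reports the model R^2, F and p of the overall regression and the
    Durbin–Watson statistic of the residuals.
    """
    x = np.asarray(predictor, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    if np.var(x) == 0:
        raise ValueError("predictor has zero variance")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return SimpleRegressionResult(
        r2=float(res.rsquared), f=float(res.fvalue), p=float(res.f_pvalue),
        durbin_watson=float(durbin_watson(res.resid)),
        coef=float(res.params[1]), intercept=float(res.params[0]), n=x.size)


@dataclass(frozen=True)
class ModerationResult:
    """OLS moderation fit with HC3-robust covariance.

    Coefficient order: (intercept, predictor, moderator, interaction).
    """

    coefficients: np.ndarray
    cov_hc3: np.ndarray
    r2: float
    delta_r2: float
    f_interaction: float
    p_interaction: float
    n: int
    moderator_values: np.ndarray = field(repr=False, default=None)
    _sm_result: object = field(repr=False, default=None, compare=False)

    @property
    def df_resid(self) -> int:
        return self.n - 4

    def conditional_effect(self, w):
        """theta(w) = b1 + b3 * w and its HC3 standard error."""
        w = np.asarray(w, dtype=float)
        b = self.coefficients
        theta = b[1] + b[3] * w
        v = self.cov_hc3
        var = v[1, 1] + 2.0 * w * v[1, 3] + w ** 2 * v[3, 3]
        return theta, np.sqrt(var)


def moderation_fit(predictor, moderator, outcome) -> ModerationResult:
    """Fit Y ~ X + W + X*W (uncentered) with HC3-robust inference.

    The interaction F is the HC3 Wald test of the interaction coefficient
    (1 numerator df); delta R^2 compares against the no-interaction model.
    """
    x = np.asarray(predictor, dtype=float)
    w = np.asarray(moderator, dtype=float)
    y = np.asarray(outcome, dtype=float)
    n = y.size
    if n < 5:
        raise ValueError("need at least 5 observations")
    X_full = np.column_stack([np.ones(n), x, w, x * w])
    if np.linalg.cond(X_full.T @ X_full) > 1e10:
        raise ValueError("design matrix is ill-conditioned (collinearity)")
    full = sm.OLS(y, X_full).fit(cov_type="HC3")
    reduced = sm.OLS(y, X_full[:, :3]).fit()
    wald = full.wald_test(np.array([[0.0, 0.0, 0.0, 1.0]]), use_f=True,
                          scalar=True)
    r2_full = float(sm.OLS(y, X_full).fit().rsquared)
    return ModerationResult(
        coefficients=np.asarray(full.params, dtype=float),
        cov_hc3=np.asarray(full.cov_params(), dtype=float),
        r2=r2_full,
        delta_r2=r2_full - float(reduced.rsquared),
        f_interaction=float(wald.statistic),
        p_interaction=float(wald.pvalue),
        n=n, moderator_values=w, _sm_result=full)


@dataclass(frozen=True)
class JNOutput:
    boundaries: tuple
    table: pd.DataFrame
    t_crit: float
    alpha: float


def johnson_neyman(fit: ModerationResult, moderator_range=None, alpha=0.05,
                   probe_grid=None) -> JNOutput:
    """Johnson–Neyman regions of significance for the conditional effect.

    Solves (b1 + b3 w)^2 = t_crit^2 (v11 + 2 w v13 + w^2 v33) for w (a
    quadratic with v from the HC3 covariance); real roots inside the observed
    moderator range are the significance boundaries. A probe table reports
    theta(w), its HC3 confidence interval, t and p over a grid of moderator
    values.
    """
    b = fit.coefficients
    v = fit.cov_hc3
    t_crit = float(stats.t.ppf(1.0 - alpha / 2.0, fit.df_resid))
    if moderator_range is None:
        if fit.moderator_values is None:
            raise ValueError("moderator_range required")
        moderator_range = (float(fit.moderator_values.min()),
                           float(fit.moderator_values.max()))
    lo, hi = moderator_range

    a2 = b[3] ** 2 - t_crit ** 2 * v[3, 3]
    a1 = 2.0 * (b[1] * b[3] - t_crit ** 2 * v[1, 3])
    a0 = b[1] ** 2 - t_crit ** 2 * v[1, 1]
    roots = np.roots([a2, a1, a0]) if abs(a2) > 0 or abs(a1) > 0 else np.array([])
    real = sorted(float(r.real) for r in roots
                  if abs(r.imag) < 1e-9 and lo <= r.real <= hi)

    if probe_grid is None:
        probe_grid = np.linspace(lo, hi, 11)
    grid = np.sort(np.unique(np.concatenate([np.asarray(probe_grid, float),
                                             np.asarray(real)])))
    theta, se = fit.conditional_effect(grid)
    t = theta / se
    p = 2.0 * stats.t.sf(np.abs(t), fit.df_resid)
    table = pd.DataFrame({
        "moderator": grid, "effect": theta,
        "ci_lower": theta - t_crit * se, "ci_upper": theta + t_crit * se,
        "t": t, "p": p})
    return JNOutput(boundaries=tuple(real), table=table, t_crit=t_crit,
                    alpha=alpha)


@dataclass(frozen=True)
class FDRFamily:
    """One Benjamini–Hochberg correction family.

    ``adjusted`` is the rank-scaled adjustment p_(k) * m / rank(k) without the
    cumulative-minimum monotonicity step — a common reporting variant for
    corrected p-values, with values above 0.999 displayed as
    "> 0.999". ``adjusted_monotone`` is the standard (monotone) BH adjustment
    and ``significant`` the step-up decision at level q.
    """

    raw: np.ndarray
    adjusted: np.ndarray
    adjusted_monotone: np.ndarray
    significant: np.ndarray
    q: float
    name: str = ""

    def formatted(self, cap=0.999, decimals=3):
        return ["> 0.999" if a > cap else f"{a:.{decimals}f}"
                for a in self.adjusted]


def bh_adjust(p_values, q=0.05, name="") -> FDRFamily:
    """Benjamini–Hochberg adjustment of one p-value family.

    See :class:`FDRFamily` for the two adjustment variants reported.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranks = np.empty(m, dtype=int)
    ranks[order] = np.arange(1, m + 1)
    adjusted = p * m / ranks
    significant, adj_mono = multipletests(p, alpha=q, method="fdr_bh")[:2]
    return FDRFamily(raw=p, adjusted=adjusted, adjusted_monotone=adj_mono,
                     significant=significant, q=q, name=name)


def cooks_distance(fit) -> np.ndarray:
    """Cook's distance per observation of a moderation or simple OLS fit."""
    if isinstance(fit, ModerationResult):
        res = fit._sm_result
    else:
        res = fit
    ols = sm.OLS(res.model.endog, res.model.exog).fit()
    return ols.get_influence().cooks_distance[0]


def simple_slopes(fit: ModerationResult, probes=None, alpha=0.05):
    """Conditional effects at probe moderator values (default mean +/- 1 SD).

    Returns a DataFrame with the effect, HC3 confidence interval, t and p at
    each probe value.
    """
    if probes is None:
        w = fit.moderator_values
        if w is None:
            raise ValueError("probes required when moderator values unknown")
        mu, sd = float(np.mean(w)), float(np.std(w, ddof=1))
        probes = np.array([mu - sd, mu, mu + sd])
    probes = np.asarray(probes, dtype=float)
    theta, se = fit.conditional_effect(probes)
    t_crit = float(stats.t.ppf(1.0 - alpha / 2.0, fit.df_resid))
    t = theta / se
    p = 2.0 * stats.t.sf(np.abs(t), fit.df_resid)
    return pd.DataFrame({"moderator": probes, "effect": theta,
                         "ci_lower": theta - t_crit * se,
                         "ci_upper": theta + t_crit * se, "t": t, "p": p})


class AgeModeration(BaseEstimator):
    """Age-moderated regression as an estimator.

    ``fit(X, y)`` expects X with two columns (predictor, age) and the
    behavioral slope as y. Fitted attributes expose the coefficients, HC3
    covariance, interaction test, Johnson–Neyman output and simple slopes.
    """

    def __init__(self, alpha=0.05, probe_step=0.6):
        self.alpha = alpha
        self.probe_step = probe_step

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must have columns (predictor, moderator)")
        self.result_ = moderation_fit(X[:, 0], X[:, 1], np.asarray(y, float))
        self.coef_ = self.result_.coefficients
        self.interaction_ = float(self.coef_[3])
        self.p_interaction_ = self.result_.p_interaction
        self.jn_ = johnson_neyman(self.result_, alpha=self.alpha)
        self.simple_slopes_ = simple_slopes(self.result_, alpha=self.alpha)
        self.cooks_d_ = cooks_distance(self.result_)
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        b = self.coef_
        return b[0] + b[1] * X[:, 0] + b[2] * X[:, 1] + b[3] * X[:, 0] * X[:, 1]
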