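"""Behavioral modelling of event segmentation.

The outcome is binary per 2-s movie interval: did the subject press the key
(set an event boundary) in that interval? Two models are fit:

* per subject, a binomial GLM with logit link and the number of situational
  changes as the single predictor — its slope ("coefficient estimate",
  responsiveness to situational changes) is the outcome variable of all
  downstream brain-behavior analyses;
* for the cohort, a mixed-effects logistic regression with a random intercept
  per subject, estimated by maximum likelihood with Gauss–Hermite quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special
from statsmodels.tools.numdiff import approx_hess1

__all__ = [
    "SubjectLogisticFit",
    "MixedLogisticFit",
    "fit_subject_logistic",
    "fit_mixed_logistic",
    "exclude_response_outliers",
    "odds_ratio",
]

#: consistency constant making the MAD unbiased for the SD under normality
MAD_SCALE = 1.4826


def odds_ratio(coefficient: float) -> float:
    """Odds ratio implied by a logistic coefficient: OR = exp(b)."""
    return float(np.exp(coefficient))


@dataclass(frozen=True)
class SubjectLogisticFit:
    subject_id: str
    intercept: float
    slope: float
    intercept_se: float
    slope_se: float
    converged: bool
    n_intervals: int

    @property
    def slope_or(self) -> float:
        return odds_ratio(self.slope)

    def predict_proba(self, changes):
        eta = self.intercept + self.slope * np.asarray(changes, dtype=float)
        return 1.0 / (1.0 + np.exp(-eta))


@dataclass(frozen=True)
class MixedLogisticFit:
    """Random-intercept logistic regression fit.

    ``intercept`` and ``slope`` are the fixed effects (logit scale);
    ``re_sd`` is the standard deviation of the subject random intercept.
    """

    intercept: float
    slope: float
    intercept_se: float
    slope_se: float
    re_sd: float
    loglik: float
    converged: bool
    n_subjects: int

    @property
    def odds_ratios(self):
        return {"intercept": odds_ratio(self.intercept),
                "changes": odds_ratio(self.slope)}

    def odds_ratio_ci(self, term="changes", level=0.95):
        from scipy.stats import norm
        z = norm.ppf(0.5 + level / 2.0)
        b, se = ((self.slope, self.slope_se) if term == "changes"
                 else (self.intercept, self.intercept_se))
        return float(np.exp(b - z * se)), float(np.exp(b + z * se))


def fit_subject_logistic(coding, responses, subject_id="") -> SubjectLogisticFit:
    """Maximum-likelihood binomial GLM (logit link): response ~ changes.

    Complete or quasi-complete separation (or a degenerate outcome) is flagged
    as ``converged=False``; such subjects are excluded downstream.
    """
    x = np.asarray(coding.change_counts, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape:
        raise ValueError("coding and responses must have equal length")
    if np.unique(x).size < 2 or y.min() == y.max():
        return SubjectLogisticFit(subject_id, np.nan, np.nan, np.nan, np.nan,
                                  converged=False, n_intervals=x.size)
    X = sm.add_constant(x)
    try:
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        params, bse = res.params, res.bse
        ok = bool(res.converged) and np.all(np.isfinite(params)) \
            and np.all(np.abs(params) < 50) and np.all(np.isfinite(bse))
    except Exception:
        return SubjectLogisticFit(subject_id, np.nan, np.nan, np.nan, np.nan,
                                  converged=False, n_intervals=x.size)
    return SubjectLogisticFit(subject_id, float(params[0]), float(params[1]),
                              float(bse[0]), float(bse[1]),
                              converged=ok, n_intervals=x.size)


def fits_to_frame(fits) -> pd.DataFrame:
    return pd.DataFrame(
        [{"subject_id": f.subject_id, "intercept": f.intercept, "slope": f.slope,
          "intercept_se": f.intercept_se, "slope_se": f.slope_se,
          "converged": f.converged} for f in fits])


# ---------------------------------------------------------------------------
# Mixed-effects logistic regression (random intercept)
# ---------------------------------------------------------------------------

def _cell_counts(codings, responses_list):
    """Collapse each subject's intervals into (x, y) cell counts.

    The predictor takes few distinct values, so the per-subject likelihood only
    depends on counts per (change value, outcome) cell.
    """
    cells = []
    for coding, resp in zip(codings, responses_list):
        x = np.asarray(coding.change_counts)
        y = np.asarray(resp)
        xs = np.unique(x)
        n1 = np.array([np.sum((x == v) & (y == 1)) for v in xs], dtype=float)
        n0 = np.array([np.sum((x == v) & (y == 0)) for v in xs], dtype=float)
        cells.append((xs.astype(float), n1, n0))
    return cells


def _mixed_nll(params, cells, nodes, weights):
    """Negative marginal log-likelihood via adaptive Gauss-Hermite quadrature.

    With hundreds of intervals per subject the conditional posterior of u_i is
    far narrower than N(0, sd), so the quadrature nodes are recentred at each
    subject's conditional mode and rescaled by the local curvature before the
    Hermite rule is applied (the same scheme lme4 uses for nAGQ > 1).
    """
    b0, b1, log_sd = params
    sd = np.exp(log_sd)
    var = sd * sd
    log_norm = np.log(sd) + 0.5 * np.log(2.0 * np.pi)
    log_w = np.log(weights) + nodes ** 2
    nll = 0.0
    for xs, n1, n0 in cells:
        off = b0 + b1 * xs
        n_tot = n1 + n0
        # Newton iterations for the mode of loglik(u) + log prior(u)
        u_hat = 0.0
        for _ in range(50):
            p = special.expit(off + u_hat)
            grad = np.sum(n1 - n_tot * p) - u_hat / var
            curv = -np.sum(n_tot * p * (1.0 - p)) - 1.0 / var
            step = grad / curv
            u_hat -= step
            if abs(step) < 1e-10:
                break
        p = special.expit(off + u_hat)
        tau = 1.0 / np.sqrt(np.sum(n_tot * p * (1.0 - p)) + 1.0 / var)
        u = u_hat + np.sqrt(2.0) * tau * nodes
        eta = off[:, None] + u[None, :]                  # (cells, nodes)
        integrand = (n1[:, None] * (-np.logaddexp(0.0, -eta))
                     + n0[:, None] * (-np.logaddexp(0.0, eta))).sum(axis=0)
        integrand += -0.5 * u ** 2 / var - log_norm
        nll -= (np.log(np.sqrt(2.0) * tau)
                + special.logsumexp(log_w + integrand))
    return nll


def fit_mixed_logistic(codings, responses_list, n_nodes=25) -> MixedLogisticFit:
    """Random-intercept logistic regression on stacked intervals.

    The marginal likelihood integrates the subject intercept u_i ~ N(0, sd^2)
    out with ``n_nodes``-point Gauss–Hermite quadrature; (b0, b1, log sd) are
    optimized jointly. Standard errors of the fixed effects come from the
    numerical Hessian of the negative log-likelihood at the optimum.
    """
    if len(codings) < 5:
        raise ValueError("need at least 5 subjects for the mixed model")
    cells = _cell_counts(codings, responses_list)
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)

    # pooled GLM start values
    x_all = np.concatenate([c.change_counts for c in codings]).astype(float)
    y_all = np.concatenate([np.asarray(r, float) for r in responses_list])
    pooled = sm.GLM(y_all, sm.add_constant(x_all),
                    family=sm.families.Binomial()).fit()
    x0 = np.array([pooled.params[0], pooled.params[1], np.log(0.5)])

    res = optimize.minimize(_mixed_nll, x0, args=(cells, nodes, weights),
                            method="L-BFGS-B")
    b0, b1, log_sd = res.x
    H = approx_hess1(res.x, _mixed_nll, args=(cells, nodes, weights))
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(3, np.nan)
    return MixedLogisticFit(intercept=float(b0), slope=float(b1),
                            intercept_se=float(se[0]), slope_se=float(se[1]),
                            re_sd=float(np.exp(log_sd)), loglik=float(-res.fun),
                            converged=bool(res.success), n_subjects=len(codings))


# ---------------------------------------------------------------------------
# Outlier screening
# ---------------------------------------------------------------------------

def exclude_response_outliers(response_counts, threshold=3.0):
    """Scaled-MAD screen on per-subject response counts.

    A subject is excluded iff |count - median| > threshold * 1.4826 * MAD
    (strict inequality; boundary ties are kept). When the MAD is zero the rule
    is undefined and no subject is excluded.

    Returns (kept_indices, excluded_indices).
    """
    counts = np.asarray(response_counts, dtype=float)
    if counts.size < 3:
        raise ValueError("need at least 3 subjects")
    med = np.median(counts)
    mad = np.median(np.abs(counts - med))
    if mad == 0:
        return np.arange(counts.size), np.array([], dtype=int)
    out = np.abs(counts - med) > threshold * MAD_SCALE * mad
    return np.flatnonzero(~out), np.flatnonzero(out)
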