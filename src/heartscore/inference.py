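"""Group comparisons and logistic odds-ratio tables.

Two families of analyses validate the instrument against independent
relationship measures:

* Welch two-sample t-tests (unequal variances, Satterthwaite degrees of
  freedom), one-sided in the hypothesized direction for every subscale
  except Traditional Values;
* logistic regressions of a binary indicator (any IPV, full disclosure)
  on z-scored subscale scores — five single-predictor ("unadjusted")
  fits and one five-predictor ("adjusted") fit, reported as odds ratios
  per SD with delta-method standard errors on the OR scale.

The logistic solver is iteratively reweighted least squares (Newton
scoring on the binomial log-likelihood) with step-halving, so the
deviance decreases monotonically across iterations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "WelchResult",
    "LogisticFit",
    "welch_t",
    "zscale",
    "fit_logistic",
    "or_table",
    "DEFAULT_ALTERNATIVES",
    "p_stars",
]

#: One-sided directions for the group comparisons, keyed by
#: (grouping variable, subscale).  "a_greater" means the first (reference,
#: e.g. no-IPV) group is hypothesized to have the larger mean.  TV is
#: two-sided throughout.
DEFAULT_ALTERNATIVES: dict[str, dict[str, str]] = {
    "any_ipv": {  # a = no IPV, b = IPV
        "TV": "two_sided",
        "PS": "a_greater",
        "PAC": "b_greater",
        "PR": "b_greater",
        "HPR": "a_greater",
    },
    "full_disclosure": {  # a = not fully disclosed, b = fully disclosed
        "TV": "two_sided",
        "PS": "b_greater",
        "PAC": "a_greater",
        "PR": "a_greater",
        "HPR": "b_greater",
    },
    "age_le_25": {  # a = older (>25), b = younger
        "TV": "two_sided",
        "PS": "a_greater",
        "PAC": "b_greater",
        "PR": "b_greater",
        "HPR": "a_greater",
    },
    "lives_with_partner": {  # a = not cohabiting, b = cohabiting
        "TV": "two_sided",
        "PS": "a_greater",
        "PAC": "b_greater",
        "PR": "b_greater",
        "HPR": "a_greater",
    },
}


@dataclass(frozen=True)
class WelchResult:
    diff: float  # mean_a - mean_b
    se: float
    t: float
    df: float
    p: float
    alternative: str
    n_a: int
    n_b: int


def welch_t(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    alternative: str = "two_sided",
) -> WelchResult:
    """Welch's unequal-variance t-test.

    ``alternative`` is one of ``two_sided``, ``a_greater`` (H1: the first
    sample has the larger mean), or ``b_greater``.
    """
    if alternative not in {"two_sided", "a_greater", "b_greater"}:
        raise ValueError(f"unknown alternative {alternative!r}")
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("each sample needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = a.mean() - b.mean()
    se2 = va / na + vb / nb
    if se2 == 0:
        # both samples constant: no evidence either way
        warnings.warn("zero variance in both samples; p = 1 by convention")
        df = float(na + nb - 2)
        p = 1.0 if alternative == "two_sided" else (1.0 if diff <= 0 else 0.0)
        return WelchResult(diff, 0.0, 0.0, df, 1.0, alternative, na, nb)
    se = np.sqrt(se2)
    t = diff / se
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    if alternative == "two_sided":
        p = 2.0 * stats.t.sf(abs(t), df)
    elif alternative == "a_greater":
        p = stats.t.sf(t, df)
    else:  # b_greater
        p = stats.t.cdf(t, df)
    return WelchResult(diff, se, t, df, float(p), alternative, na, nb)


def zscale(values: Sequence[float]) -> np.ndarray:
    """Standardize to mean 0, sample SD 1 (n-1 denominator)."""
    x = np.asarray(values, dtype=float)
    sd = x.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("cannot z-scale a constant input")
    return (x - x.mean()) / sd


@dataclass
class LogisticFit:
    beta: np.ndarray
    se: np.ndarray  # observed-information SEs on the log-odds scale
    odds_ratios: np.ndarray
    or_se: np.ndarray  # delta method: OR * SE_beta
    converged: bool
    n_iterations: int
    deviance: float
    deviance_trace: list[float] = field(default_factory=list)
    names: list[str] = field(default_factory=list)

    def wald_p(self) -> np.ndarray:
        z = self.beta / self.se
        return 2.0 * stats.norm.sf(np.abs(z))


def fit_logistic(
    outcome: Sequence[float],
    predictors: np.ndarray,
    intercept: bool = True,
    max_iter: int = 50,
    tol: float = 1e-8,
    names: Optional[Sequence[str]] = None,
) -> LogisticFit:
    """Binomial logistic regression via iteratively reweighted least squares.

    Converges when the relative deviance change falls below ``tol``.
    Step-halving keeps the deviance monotonically decreasing.  Complete
    or quasi-complete separation (any standardized coefficient exceeding
    10) is reported via ``converged=False`` and a warning, not repaired.
    """
    y = np.asarray(outcome, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(predictors, dtype=float))
    if X.shape[0] != y.shape[0]:
        X = X.T
    if intercept:
        X = np.column_stack([np.ones(len(y)), X])
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("outcome has a single class; logistic model undefined")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")

    def _deviance(beta: np.ndarray) -> float:
        eta = X @ beta
        # log(1 + e^eta) computed stably
        return 2.0 * float(np.sum(np.logaddexp(0.0, eta) - y * eta))

    beta = np.zeros(X.shape[1])
    dev = _deviance(beta)
    trace = [dev]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        w = np.clip(p * (1.0 - p), 1e-12, None)
        z = eta + (y - p) / w
        XtW = X.T * w
        try:
            beta_new = np.linalg.solve(XtW @ X, XtW @ z)
        except np.linalg.LinAlgError:
            warnings.warn("weighted least squares step singular; stopping")
            break
        # step-halving so the deviance never increases
        step = beta_new - beta
        dev_new = _deviance(beta + step)
        halvings = 0
        while dev_new > dev + 1e-12 and halvings < 30:
            step /= 2.0
            dev_new = _deviance(beta + step)
            halvings += 1
        beta = beta + step
        trace.append(dev_new)
        if abs(dev - dev_new) / (abs(dev) + 0.1) < tol:
            dev = dev_new
            converged = True
            break
        dev = dev_new

    eta = X @ beta
    p = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
    w = np.clip(p * (1.0 - p), 1e-12, None)
    info = (X.T * w) @ X
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    col_scale = X.std(axis=0, ddof=0)
    col_scale[col_scale == 0] = 1.0
    if np.any(np.abs(beta * col_scale) > 10.0):
        warnings.warn(
            "possible separation: a standardized coefficient exceeds 10; "
            "estimates are unreliable"
        )
        converged = False
    names = list(names) if names is not None else [f"x{j}" for j in range(X.shape[1] - int(intercept))]
    full_names = (["(intercept)"] if intercept else []) + names
    return LogisticFit(
        beta=beta,
        se=se,
        odds_ratios=np.exp(beta),
        or_se=np.exp(beta) * se,
        converged=converged,
        n_iterations=it,
        deviance=dev,
        deviance_trace=trace,
        names=full_names,
    )


def p_stars(p: float) -> str:
    """Significance stars at the 0.1 / 0.05 / 0.01 levels."""
    if p < 0.01:
        return "***"
    if p < 0.05:
        return "**"
    if p < 0.1:
        return "*"
    return ""


def or_table(
    outcome: Sequence[float],
    scores: pd.DataFrame,
    codes: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Unadjusted and adjusted odds ratios per SD of each subscale.

    ``scores`` holds raw subscale scores; each is z-scored on the
    analysis sample before fitting.  Unadjusted = five single-predictor
    models; adjusted = one model with all five predictors.
    """
    from .instrument import SUBSCALE_CODES

    codes = list(codes) if codes is not None else [c for c in SUBSCALE_CODES if c in scores]
    y = np.asarray(outcome, dtype=float)
    Z = np.column_stack([zscale(scores[c].to_numpy(dtype=float)) for c in codes])
    rows = []
    adj = fit_logistic(y, Z, names=codes)
    adj_p = adj.wald_p()
    for j, code in enumerate(codes):
        una = fit_logistic(y, Z[:, [j]], names=[code])
        p_u = una.wald_p()[1]
        p_a = adj_p[j + 1]
        rows.append(
            {
                "subscale": code,
                "or_unadjusted": una.odds_ratios[1],
                "se_unadjusted": una.or_se[1],
                "p_unadjusted": p_u,
                "stars_unadjusted": p_stars(p_u),
                "or_adjusted": adj.odds_ratios[j + 1],
                "se_adjusted": adj.or_se[j + 1],
                "p_adjusted": p_a,
                "stars_adjusted": p_stars(p_a),
            }
        )
    return pd.DataFrame(rows)
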