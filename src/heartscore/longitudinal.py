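"""Random-intercept growth models for subscale change over visits.

The default model for each subscale is the minimal linear mixed model
consistent with four linear group trajectories (baseline IPV status
crossed with receipt of the IPV counseling module):

    Y_ij = b0 + b1 * visit_ij + b2 * ipv_i + b3 * modC_i
         + b4 * visit_ij * ipv_i + b5 * visit_ij * modC_i + u_i + e_ij

with participant random intercept u_i ~ N(0, tau^2) and residual
e_ij ~ N(0, sigma^2).  Estimation is maximum likelihood via EM, treating
the random intercepts as missing data; the marginal log-likelihood is
nondecreasing across iterations by construction and is asserted at every
step.  Visits are indexed 0 (baseline), 1 (month 3), 2 (month 6); the
month-1 booster sits off the regular grid and is excluded by default.

With a single observation per participant tau^2 and sigma^2 are not
separately identified; the fit detects this and falls back to ordinary
least squares with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GrowthModelSpec",
    "GrowthFit",
    "build_growth_design",
    "fit_growth",
    "fit_growth_arrays",
    "predict_trajectories",
    "change_summary",
]

DEFAULT_TERMS = (
    "intercept",
    "visit",
    "baseline_ipv",
    "module_c",
    "visit:baseline_ipv",
    "visit:module_c",
)


@dataclass(frozen=True)
class GrowthModelSpec:
    subscale_code: str
    terms: tuple[str, ...] = DEFAULT_TERMS
    max_iter: int = 500
    tol: float = 1e-6  # relative log-likelihood change


@dataclass
class GrowthFit:
    spec: GrowthModelSpec
    beta: np.ndarray
    se: np.ndarray
    tau2: float
    sigma2: float
    loglik: float
    loglik_trace: list[float]
    converged: bool
    n_iterations: int
    n_obs: int
    n_participants: int
    term_names: list[str] = field(default_factory=list)
    ols_fallback: bool = False

    def summary(self) -> pd.DataFrame:
        from scipy import stats

        z = self.beta / self.se
        return pd.DataFrame(
            {
                "term": self.term_names,
                "estimate": self.beta,
                "se": self.se,
                "z": z,
                "p": 2 * stats.norm.sf(np.abs(z)),
            }
        )


def _marginal_loglik(
    y: np.ndarray,
    X: np.ndarray,
    beta: np.ndarray,
    tau2: float,
    sigma2: float,
    group_idx: np.ndarray,
    n_groups: int,
) -> float:
    r = y - X @ beta
    n_i = np.bincount(group_idx, minlength=n_groups).astype(float)
    s_i = np.bincount(group_idx, weights=r, minlength=n_groups)
    rss = float(r @ r)
    shrink = tau2 / (sigma2 + n_i * tau2)  # per-group Woodbury factor
    quad = (rss - np.sum(shrink * s_i**2)) / sigma2
    logdet = len(y) * np.log(sigma2) + np.sum(np.log1p(n_i * tau2 / sigma2))
    return -0.5 * (len(y) * np.log(2 * np.pi) + logdet + quad)


def fit_growth_arrays(
    y: np.ndarray,
    X: np.ndarray,
    groups: Sequence,
    term_names: Optional[Sequence[str]] = None,
    max_iter: int = 500,
    tol: float = 1e-6,
    spec: Optional[GrowthModelSpec] = None,
) -> GrowthFit:
    """EM maximum-likelihood fit of the random-intercept model.

    ``groups`` labels each row's participant.  Returns a ``GrowthFit``
    whose ``loglik_trace`` records the (nondecreasing) marginal
    log-likelihood at every EM iteration.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if len(y) != n:
        raise ValueError("y and X row counts differ")
    codes, uniq = pd.factorize(np.asarray(groups))
    q = len(uniq)
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("singular growth-model design")
    names = list(term_names) if term_names is not None else [f"b{j}" for j in range(p)]
    spec = spec or GrowthModelSpec(subscale_code="", max_iter=max_iter, tol=tol)

    n_i = np.bincount(codes, minlength=q).astype(float)
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta

    if n_i.max() <= 1:
        warnings.warn(
            "one observation per participant: tau^2 and sigma^2 are not "
            "separately identified; falling back to ordinary least squares"
        )
        sigma2 = float(resid @ resid) / max(n - p, 1)
        cov = sigma2 * np.linalg.inv(XtX)
        ll = _marginal_loglik(y, X, beta, 0.0, max(sigma2, 1e-12), codes, q)
        return GrowthFit(
            spec=spec,
            beta=beta,
            se=np.sqrt(np.diag(cov)),
            tau2=0.0,
            sigma2=sigma2,
            loglik=ll,
            loglik_trace=[ll],
            converged=True,
            n_iterations=0,
            n_obs=n,
            n_participants=q,
            term_names=names,
            ols_fallback=True,
        )

    sigma2 = max(float(resid @ resid) / max(n - p, 1), 1e-10)
    # initial split: half the residual variance between participants
    tau2 = 0.5 * sigma2
    sigma2 = 0.5 * sigma2

    ll = _marginal_loglik(y, X, beta, tau2, sigma2, codes, q)
    trace = [ll]
    converged = False
    it = 0
    for it in range(1, (spec.max_iter or max_iter) + 1):
        # E-step: posterior mean/variance of each random intercept
        r = y - X @ beta
        s_i = np.bincount(codes, weights=r, minlength=q)
        if tau2 > 0:
            v_i = 1.0 / (1.0 / tau2 + n_i / sigma2)
            m_i = v_i * s_i / sigma2
        else:
            v_i = np.zeros(q)
            m_i = np.zeros(q)
        # M-step: beta from the de-shrunk working response, then variances
        y_star = y - m_i[codes]
        beta = np.linalg.solve(XtX, X.T @ y_star)
        r_new = y - X @ beta
        e = r_new - m_i[codes]
        sigma2 = max((float(e @ e) + float(n_i @ v_i)) / n, 1e-12)
        tau2 = max(float(np.mean(m_i**2 + v_i)), 0.0)
        ll_new = _marginal_loglik(y, X, beta, tau2, sigma2, codes, q)
        # EM guarantee: the marginal log-likelihood never decreases
        assert ll_new >= ll - 1e-8 * (1.0 + abs(ll)), (
            f"EM log-likelihood decreased: {ll} -> {ll_new}"
        )
        trace.append(ll_new)
        if abs(ll_new - ll) / (abs(ll) + 1.0) < (spec.tol or tol):
            ll = ll_new
            converged = True
            break
        ll = ll_new
    if not converged:
        warnings.warn(f"growth model did not converge in {it} iterations")

    # EM only approaches the tau^2 = 0 boundary geometrically; adopt the
    # boundary solution (plain OLS) outright whenever it is at least as
    # likely as where EM stopped
    beta_ols = np.linalg.solve(XtX, X.T @ y)
    r_ols = y - X @ beta_ols
    sigma2_ols = max(float(r_ols @ r_ols) / n, 1e-12)
    ll_boundary = _marginal_loglik(y, X, beta_ols, 0.0, sigma2_ols, codes, q)
    if ll_boundary >= ll - 1e-10 * (1.0 + abs(ll)):
        beta, tau2, sigma2, ll = beta_ols, 0.0, sigma2_ols, ll_boundary
        trace.append(ll_boundary)
        converged = True

    # GLS information for the fixed effects at the final variances
    shrink = tau2 / (sigma2 + n_i * tau2)
    Xsum = np.zeros((q, p))
    np.add.at(Xsum, codes, X)
    info = (XtX - (Xsum * shrink[:, None]).T @ Xsum) / sigma2
    cov = np.linalg.inv(info)
    return GrowthFit(
        spec=spec,
        beta=beta,
        se=np.sqrt(np.diag(cov)),
        tau2=tau2,
        sigma2=sigma2,
        loglik=ll,
        loglik_trace=trace,
        converged=converged,
        n_iterations=it,
        n_obs=n,
        n_participants=q,
        term_names=names,
    )


def build_growth_design(
    long_scores: pd.DataFrame,
    covariates: pd.DataFrame,
    subscale_code: str,
    terms: Sequence[str] = DEFAULT_TERMS,
    include_booster: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Assemble (y, X, groups) for one subscale's growth model.

    ``long_scores`` is a scored-cohort table (participant_id, visit,
    visit_index, one column per subscale); ``covariates`` carries
    baseline ``any_ipv`` and ``modules_received`` per participant.
    Baseline covariates are propagated to every visit.  Booster (month 1)
    rows are excluded unless requested.
    """
    df = long_scores.copy()
    if not include_booster:
        df = df[df["visit_index"].isin([0.0, 1.0, 2.0])]
    df = df[df[f"{subscale_code}_valid"]] if f"{subscale_code}_valid" in df else df
    df = df.dropna(subset=[subscale_code])

    base = covariates[covariates["visit"] == "baseline"].set_index("participant_id")
    ipv = base["any_ipv"].map({"yes": 1.0, "no": 0.0})
    if "modules_received" in base:
        modc = base["modules_received"].map(
            lambda m: 1.0 if (isinstance(m, str) and "C" in m) or (isinstance(m, (list, tuple, set)) and "C" in m) else 0.0
        )
    else:
        modc = pd.Series(0.0, index=base.index)
    df = df[df["participant_id"].isin(base.index)]

    visit = df["visit_index"].to_numpy(dtype=float)
    ipv_v = ipv.reindex(df["participant_id"]).to_numpy(dtype=float)
    modc_v = modc.reindex(df["participant_id"]).to_numpy(dtype=float)
    pieces = {
        "intercept": np.ones(len(df)),
        "visit": visit,
        "baseline_ipv": ipv_v,
        "module_c": modc_v,
        "visit:baseline_ipv": visit * ipv_v,
        "visit:module_c": visit * modc_v,
    }
    unknown = [t for t in terms if t not in pieces]
    if unknown:
        raise ValueError(f"unknown growth-model terms: {unknown}")
    X = np.column_stack([pieces[t] for t in terms])
    y = df[subscale_code].to_numpy(dtype=float)
    ok = ~np.isnan(X).any(axis=1) & ~np.isnan(y)
    return y[ok], X[ok], df["participant_id"].to_numpy()[ok], list(terms)


def fit_growth(
    long_scores: pd.DataFrame,
    covariates: pd.DataFrame,
    spec: GrowthModelSpec,
) -> GrowthFit:
    """Fit the growth model for one subscale from scored tables."""
    y, X, groups, names = build_growth_design(
        long_scores, covariates, spec.subscale_code, spec.terms
    )
    return fit_growth_arrays(
        y, X, groups, term_names=names, max_iter=spec.max_iter, tol=spec.tol, spec=spec
    )


def predict_trajectories(
    fit: GrowthFit,
    visits: Sequence[float] = (0.0, 1.0, 2.0),
) -> pd.DataFrame:
    """Fixed-effect predicted means for the four IPV-by-module groups.

    Rows: (baseline_ipv, module_c, visit, predicted).  Terms absent from
    the fitted model contribute zero.
    """
    rows = []
    idx = {t: j for j, t in enumerate(fit.term_names)}

    def _val(term: str, pieces: Mapping[str, float]) -> float:
        return pieces.get(term, 0.0)

    for ipv in (0.0, 1.0):
        for modc in (0.0, 1.0):
            for v in visits:
                pieces = {
                    "intercept": 1.0,
                    "visit": v,
                    "baseline_ipv": ipv,
                    "module_c": modc,
                    "visit:baseline_ipv": v * ipv,
                    "visit:module_c": v * modc,
                }
                pred = sum(fit.beta[j] * _val(t, pieces) for t, j in idx.items())
                rows.append(
                    {
                        "baseline_ipv": int(ipv),
                        "module_c": int(modc),
                        "visit": v,
                        "predicted": pred,
                    }
                )
    return pd.DataFrame(rows)


def change_summary(long_scores: pd.DataFrame, codes: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Descriptive mean changes baseline -> month 3 -> month 6.

    Participants missing either visit of a pair are excluded pairwise;
    the paired n is reported for each contrast.
    """
    from .instrument import SUBSCALE_CODES

    codes = list(codes) if codes is not None else [c for c in SUBSCALE_CODES if c in long_scores]
    wide = {
        v: long_scores[long_scores["visit_index"] == v].set_index("participant_id")
        for v in (0.0, 1.0, 2.0)
    }
    rows = []
    pairs = [(0.0, 1.0, "baseline->month3"), (1.0, 2.0, "month3->month6"), (0.0, 2.0, "baseline->month6")]
    for code in codes:
        for va, vb, label in pairs:
            a = wide[va][code].dropna()
            b = wide[vb][code].dropna()
            common = a.index.intersection(b.index)
            delta = b.loc[common] - a.loc[common]
            rows.append(
                {
                    "subscale": code,
                    "contrast": label,
                    "mean_change": delta.mean() if len(common) else np.nan,
                    "sd_change": delta.std(ddof=1) if len(common) > 1 else np.nan,
                    "n_pairs": len(common),
                }
            )
    return pd.DataFrame(rows)
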