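"""Internal-consistency reliability and subscale correlation structure.

Three classical reliability coefficients are computed per subscale:

* raw Cronbach's alpha from item covariances,
  ``alpha = k/(k-1) * (1 - sum_i s_i^2 / s_T^2)``;
* standardized alpha from the item correlation matrix,
  ``k rbar / (1 + (k-1) rbar)`` with ``rbar`` the mean off-diagonal
  correlation;
* Guttman's lambda-6 from squared multiple correlations,
  ``1 - sum_j (1 - smc_j) / V_T`` with ``smc_j = 1 - 1/(R^-1)_jj`` and
  ``V_T`` the sum of all entries of ``R``.

Reliability is computed on listwise-complete item matrices by default:
the coefficients describe the instrument as answered, not the imputed
data.  Subscale-score correlations use pairwise-complete observations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .instrument import InstrumentSpec, ResponseRecord, orient_responses

__all__ = [
    "ReliabilityResult",
    "CorrelationComparison",
    "item_matrix",
    "cronbach_alpha",
    "standardized_alpha",
    "guttman_lambda6",
    "reliability_table",
    "subscale_correlations",
    "compare_samples",
]


def item_matrix(
    records: Sequence[ResponseRecord],
    instrument: InstrumentSpec,
    subscale_code: str,
    listwise: bool = True,
    orient: bool = True,
) -> np.ndarray:
    """Oriented respondents-by-items matrix for one subscale.

    With ``listwise=True`` (default) rows with any missing item are
    dropped; otherwise missing entries are imputed with the row mean of
    the available items in the subscale (mirroring the scoring rule).
    """
    sub = instrument.subscale(subscale_code)
    rows = []
    for rec in records:
        oriented = orient_responses(rec, instrument) if orient else rec
        rows.append([oriented.responses.get(iid, None) for iid in sub.item_ids])
    X = np.array(rows, dtype=float)  # None -> nan
    if X.size == 0:
        return X.reshape(0, sub.n_items)
    if listwise:
        return X[~np.isnan(X).any(axis=1)]
    row_mean = np.nanmean(np.where(np.isnan(X).all(axis=1)[:, None], np.nan, X), axis=1)
    keep = ~np.isnan(row_mean)
    X = X[keep]
    idx = np.where(np.isnan(X))
    X[idx] = np.take(np.nanmean(X, axis=1), idx[0])
    return X


def _check_matrix(X: np.ndarray) -> None:
    if X.ndim != 2 or X.shape[0] < 3 or X.shape[1] < 2:
        raise ValueError(
            f"need >= 3 respondents and >= 2 items, got shape {getattr(X, 'shape', None)}"
        )


def cronbach_alpha(X: np.ndarray) -> float:
    """Raw Cronbach's alpha from an n x k complete item matrix."""
    X = np.asarray(X, dtype=float)
    _check_matrix(X)
    if np.isnan(X).any():
        raise ValueError("item matrix contains missing values; delete or impute first")
    k = X.shape[1]
    item_vars = X.var(axis=0, ddof=1)
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("total-score variance is zero; alpha undefined")
    return k / (k - 1) * (1.0 - item_vars.sum() / total_var)


def standardized_alpha(R: np.ndarray) -> float:
    """Standardized alpha from a k x k item correlation matrix."""
    R = np.asarray(R, dtype=float)
    k = R.shape[0]
    if R.shape != (k, k) or k < 2:
        raise ValueError("need a square correlation matrix with k >= 2")
    off = R[~np.eye(k, dtype=bool)]
    rbar = off.mean()
    denom = 1.0 + (k - 1) * rbar
    if denom <= 0:
        raise ValueError(f"mean inter-item correlation {rbar:.4f} <= -1/(k-1); alpha undefined")
    return k * rbar / denom


def guttman_lambda6(R: np.ndarray) -> float:
    """Guttman's lambda-6 from a k x k item correlation matrix."""
    R = np.asarray(R, dtype=float)
    k = R.shape[0]
    if R.shape != (k, k) or k < 2:
        raise ValueError("need a square correlation matrix with k >= 2")
    try:
        Rinv = np.linalg.inv(R)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "correlation matrix is singular (perfectly collinear items); "
            "drop redundant items before computing lambda-6"
        ) from exc
    smc = 1.0 - 1.0 / np.diag(Rinv)
    V_t = R.sum()
    return 1.0 - np.sum(1.0 - smc) / V_t


@dataclass(frozen=True)
class ReliabilityResult:
    subscale_code: str
    raw_alpha: float
    std_alpha: float
    lambda6: float
    n_respondents: int
    n_items: int


def reliability_table(
    records: Sequence[ResponseRecord],
    instrument: InstrumentSpec,
    listwise: bool = True,
) -> pd.DataFrame:
    """Per-subscale reliability summary (raw alpha, std alpha, G6, n)."""
    out = []
    for sub in instrument.subscales:
        X = item_matrix(records, instrument, sub.code, listwise=listwise)
        R = np.corrcoef(X, rowvar=False)
        res = ReliabilityResult(
            subscale_code=sub.code,
            raw_alpha=cronbach_alpha(X),
            std_alpha=standardized_alpha(R),
            lambda6=guttman_lambda6(R),
            n_respondents=X.shape[0],
            n_items=X.shape[1],
        )
        out.append(res.__dict__)
    return pd.DataFrame(out)


def subscale_correlations(scores: pd.DataFrame, codes: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Pearson correlation matrix of subscale scores, pairwise-complete.

    ``scores`` is a scored-cohort table with one column per subscale
    code.  Constant columns yield NaN entries (reported as absent).
    """
    from .instrument import SUBSCALE_CODES

    codes = list(codes) if codes is not None else [c for c in SUBSCALE_CODES if c in scores]
    if len(scores) < 3:
        raise ValueError("need at least 3 score vectors")
    sub = scores[codes].astype(float)
    return sub.corr(method="pearson", min_periods=3)


@dataclass(frozen=True)
class CorrelationComparison:
    sample_a: pd.DataFrame
    sample_b: pd.DataFrame
    difference: pd.DataFrame
    sign_agreement: pd.DataFrame


def compare_samples(matrix_a: pd.DataFrame, matrix_b: pd.DataFrame) -> CorrelationComparison:
    """Pair two subscale correlation matrices (e.g. survey vs pilot)."""
    if list(matrix_a.index) != list(matrix_b.index) or list(matrix_a.columns) != list(
        matrix_b.columns
    ):
        raise ValueError("correlation matrices must share subscale ordering")
    diff = matrix_a - matrix_b
    sign = np.sign(matrix_a) == np.sign(matrix_b)
    return CorrelationComparison(
        sample_a=matrix_a,
        sample_b=matrix_b,
        difference=diff,
        sign_agreement=pd.DataFrame(sign, index=matrix_a.index, columns=matrix_a.columns),
    )
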