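"""Synthetic cohorts with the statistical structure the analyses assume.

No participant-level data from the original studies is available, so
every analysis module is exercised on simulated cohorts built to match
the published summary statistics: per-subscale score means and SDs,
internal-consistency reliabilities (Cronbach's alpha), the subscale
correlation structure, item missingness, binary IPV/disclosure outcomes
linked to the scores, and three-visit score trajectories with
counseling-module interactions.

Measurement model
-----------------
Each subscale is a set of *parallel* items: a single latent factor with
equal loadings and equal noise.  For a k-item scale with inter-item
correlation rho, Cronbach's alpha follows the Spearman-Brown relation
``alpha = k rho / (1 + (k-1) rho)``, inverted by
:func:`solve_parallel_rho` to pick rho from a target alpha.

Continuous item values are discretized to the 6-point response codes by
rounding to the nearest code (equally spaced thresholds) and clipping to
[1, 6].  Discretization both attenuates correlations and distorts means
near the floor/ceiling, so the continuous location, scale, and
inter-item correlation are *moment-matched*: a numerical solve (normal
CDF cell probabilities plus Gauss-Hermite quadrature over the common
factor) picks them such that the discretized items hit the target item
mean, the target summed-score SD, and the target alpha in expectation.

Because observed summed scores are noisy measurements of the latent
factor, a latent correlation L produces an observed score correlation of
``L * sqrt(alpha_a * alpha_b)``.  The configured correlation targets are
on the *observed score* scale (what a correlation matrix of scored data
shows); the generator disattenuates them internally before drawing the
latent factors.

Everything is reproducible bit-for-bit from (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy import optimize
from scipy.stats import norm

from .instrument import SUBSCALE_CODES, CovariateRecord, InstrumentSpec, Polarity, ResponseRecord, load_instrument

__all__ = [
    "PILOT_TARGETS",
    "SURVEY_TARGETS",
    "SubscaleTarget",
    "OutcomeModel",
    "LongitudinalEffects",
    "SyntheticCohortSpec",
    "SyntheticCohort",
    "solve_parallel_rho",
    "spearman_brown",
    "generate_latent",
    "generate_items",
    "generate_outcomes",
    "generate_cohort",
    "generate_longitudinal",
]


def spearman_brown(rho: float, k: int) -> float:
    """Reliability of a k-item parallel scale with inter-item correlation rho."""
    return k * rho / (1.0 + (k - 1) * rho)


def solve_parallel_rho(alpha_target: float, k: int) -> float:
    """Invert the Spearman-Brown relation: rho = alpha / (k - alpha (k-1))."""
    if not (0.0 < alpha_target < 1.0):
        raise ValueError("alpha target must lie strictly between 0 and 1")
    if k < 2:
        raise ValueError("need k >= 2 items")
    return alpha_target / (k - alpha_target * (k - 1))


class SubscaleTarget(BaseModel):
    mean: float
    sd: float
    alpha: float

    @model_validator(mode="after")
    def _check(self) -> "SubscaleTarget":
        if self.sd <= 0:
            raise ValueError("target sd must be > 0")
        if not (0 < self.alpha < 1):
            raise ValueError("target alpha must be in (0, 1)")
        return self


#: Published summary targets for the two samples.
PILOT_TARGETS: dict[str, SubscaleTarget] = {
    "TV": SubscaleTarget(mean=26.2, sd=12.5, alpha=0.84),
    "PS": SubscaleTarget(mean=49.0, sd=9.4, alpha=0.79),
    "PAC": SubscaleTarget(mean=15.3, sd=7.3, alpha=0.74),
    "PR": SubscaleTarget(mean=8.5, sd=5.5, alpha=0.83),
    "HPR": SubscaleTarget(mean=28.7, sd=2.4, alpha=0.54),
}
SURVEY_TARGETS: dict[str, SubscaleTarget] = {
    "TV": SubscaleTarget(mean=31.7, sd=13.9, alpha=0.84),
    "PS": SubscaleTarget(mean=46.2, sd=10.3, alpha=0.81),
    "PAC": SubscaleTarget(mean=19.5, sd=9.5, alpha=0.81),
    "PR": SubscaleTarget(mean=10.5, sd=6.5, alpha=0.80),
    "HPR": SubscaleTarget(mean=27.3, sd=3.7, alpha=0.68),
}

# Observed-score correlation targets.  PAC-PS and PAC-PR are published
# for both samples; the remaining cells are modeller's choices consistent
# with the reported qualitative pattern (inverse HPR relationships
# stronger in the pilot, TV-PS positive and weaker in the pilot) and with
# positive definiteness of the implied latent structure — the strong
# PS/PAC/PR triangle leaves the TV cells little room, so they are kept
# near zero against PAC and PR.
_PILOT_CORR = np.array(
    [
        # TV     PS     PAC    PR     HPR
        [1.00, 0.15, -0.03, 0.03, -0.08],
        [0.15, 1.00, -0.63, -0.49, 0.24],
        [-0.03, -0.63, 1.00, 0.52, -0.27],
        [0.03, -0.49, 0.52, 1.00, -0.29],
        [-0.08, 0.24, -0.27, -0.29, 1.00],
    ]
)
_SURVEY_CORR = np.array(
    [
        [1.00, 0.25, -0.02, 0.05, -0.04],
        [0.25, 1.00, -0.64, -0.48, 0.22],
        [-0.02, -0.64, 1.00, 0.53, -0.16],
        [0.05, -0.48, 0.53, 1.00, -0.18],
        [-0.04, 0.22, -0.16, -0.18, 1.00],
    ]
)

#: Canonical item counts per subscale (the default instrument).
_N_ITEMS = {"TV": 13, "PS": 10, "PAC": 9, "PR": 5, "HPR": 5}


class OutcomeModel(BaseModel):
    """Logistic model for a binary covariate on z-scored latent scores."""

    intercept: float
    coefficients: dict[str, float] = Field(default_factory=dict)


class LongitudinalEffects(BaseModel):
    """Per-subscale trajectory parameters on the summed-score scale.

    ``visit_effect`` is the mean change per visit-index unit for all
    participants; ``visit_x_module_c`` and ``visit_x_ipv`` add to the
    slope for participants who received the IPV module or reported IPV
    at baseline; ``residual_sd`` is fresh within-participant noise per
    follow-up visit (the baseline latent acts as the persistent random
    intercept).
    """

    visit_effect: dict[str, float] = Field(
        default_factory=lambda: {"TV": -1.5, "PS": 1.5, "PAC": -1.0, "PR": -0.8, "HPR": 0.3}
    )
    visit_x_module_c: dict[str, float] = Field(
        default_factory=lambda: {"TV": 0.0, "PS": 0.0, "PAC": -1.5, "PR": 0.0, "HPR": 0.0}
    )
    visit_x_ipv: dict[str, float] = Field(
        default_factory=lambda: {"TV": 0.0, "PS": 0.8, "PAC": -0.8, "PR": -0.5, "HPR": 0.0}
    )
    residual_sd: dict[str, float] = Field(
        default_factory=lambda: {"TV": 4.0, "PS": 3.0, "PAC": 2.5, "PR": 2.0, "HPR": 1.0}
    )


class SyntheticCohortSpec(BaseModel):
    """All distributional targets and seeds for the simulator."""

    n_participants: int = 95
    reference: str = "pilot"  # which target column the cohort emulates
    targets: dict[str, SubscaleTarget] = Field(default_factory=lambda: dict(PILOT_TARGETS))
    correlation: Optional[list[list[float]]] = None  # observed-score scale, TV/PS/PAC/PR/HPR order
    missingness: float = 0.02  # MCAR per item
    ipv_model: OutcomeModel = Field(
        default_factory=lambda: OutcomeModel(
            intercept=-1.95, coefficients={"PS": -0.10, "PAC": 0.105, "PR": 0.135}
        )
    )
    disclosure_model: OutcomeModel = Field(
        default_factory=lambda: OutcomeModel(
            intercept=0.5, coefficients={"PS": 0.058, "PR": -0.105}
        )
    )
    p_lives_with_partner: float = 0.39
    p_age_le_25: float = 0.26
    p_new_partner: float = 0.08
    longitudinal: LongitudinalEffects = Field(default_factory=LongitudinalEffects)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SyntheticCohortSpec":
        if self.reference not in {"pilot", "survey"}:
            raise ValueError("reference must be 'pilot' or 'survey'")
        if self.reference == "survey" and self.targets == dict(PILOT_TARGETS):
            self.targets = dict(SURVEY_TARGETS)
        missing = [c for c in SUBSCALE_CODES if c not in self.targets]
        if missing:
            raise ValueError(f"targets missing subscales {missing}")
        if not (0.0 <= self.missingness <= 1.0):
            raise ValueError("missingness must lie in [0, 1]")
        R = self.correlation_matrix()
        if not np.allclose(R, R.T) or not np.allclose(np.diag(R), 1.0):
            raise ValueError("correlation matrix must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(self.latent_correlation()).min() <= 1e-10:
            raise ValueError("disattenuated latent correlation matrix is not positive definite")
        return self

    def correlation_matrix(self) -> np.ndarray:
        if self.correlation is not None:
            return np.asarray(self.correlation, dtype=float)
        return _PILOT_CORR if self.reference == "pilot" else _SURVEY_CORR

    def latent_correlation(self) -> np.ndarray:
        """Latent factor correlations that realize the observed targets.

        Discretization and measurement noise attenuate the correlation
        between two observed summed scores relative to their latent
        factors.  For factor correlation ``L`` the cross-scale item
        covariance is ``sum_n n! c_n^A c_n^B L^n`` over the Hermite
        coefficients ``c_n`` of each scale's conditional item mean
        ``g(z)``; the required ``L`` is recovered per pair by a 1-D
        root solve.  The resulting matrix must be positive definite —
        observed targets that demand a non-PD latent structure are
        rejected at validation.
        """
        R = self.correlation_matrix()
        coeffs = {}
        for c in SUBSCALE_CODES:
            t = self.targets[c]
            coeffs[c] = _hermite_coeffs(t.mean, t.sd, t.alpha, _N_ITEMS[c])
        L = np.eye(len(SUBSCALE_CODES))
        for i, a in enumerate(SUBSCALE_CODES):
            for j in range(i + 1, len(SUBSCALE_CODES)):
                b = SUBSCALE_CODES[j]
                ta, tb = self.targets[a], self.targets[b]
                target_cov = R[i, j] * ta.sd * tb.sd / (_N_ITEMS[a] * _N_ITEMS[b])
                L[i, j] = L[j, i] = _solve_pair_latent(coeffs[a], coeffs[b], target_cov)
        return L


# ---------------------------------------------------------------------------
# moment-matched discretization


_CODES = np.arange(1, 7, dtype=float)
_CUTS = np.arange(1.5, 6.0, 1.0)
_GH_X, _GH_W = np.polynomial.hermite_e.hermegauss(61)
_GH_W = _GH_W / _GH_W.sum()


def _discretized_moments(mu: float, s: float, rho: float) -> tuple[float, float, float]:
    """(mean, var, within-scale cov) of round+clip items that share a factor.

    Item j is ``mu + s*(sqrt(rho) z + sqrt(1-rho) e_j)`` discretized to
    codes 1..6.  Conditional on the common factor z the items are
    independent, so the within-scale covariance is Var(E[d|z]),
    integrated over z by Gauss-Hermite quadrature.
    """
    sz = s * np.sqrt(rho)
    se = s * np.sqrt(max(1.0 - rho, 1e-12))
    cond_mu = mu + sz * _GH_X
    P = norm.cdf((_CUTS[None, :] - cond_mu[:, None]) / se)
    P = np.diff(
        np.concatenate([np.zeros((len(_GH_X), 1)), P, np.ones((len(_GH_X), 1))], axis=1), axis=1
    )
    g = P @ _CODES
    h = P @ (_CODES**2)
    m = float(_GH_W @ g)
    var = float(_GH_W @ h) - m * m
    cov = float(_GH_W @ (g * g)) - m * m
    return m, var, cov


@lru_cache(maxsize=64)
def _calibrate_discretization(
    mean: float, sd: float, alpha: float, k: int
) -> tuple[float, float, float]:
    """Continuous (mu, s, rho) whose discretized items hit the targets.

    Targets: item mean = mean/k; summed-score variance = sd^2; raw alpha
    = alpha.  The latter two pin down the item variance v and within-
    scale covariance c via Var_sum = k v + k(k-1) c and
    alpha = k c / (v + (k-1) c).
    """
    m_t = mean / k
    denom = k - alpha * (k - 1)
    v_t = (sd * sd / k) / (1.0 + (k - 1) * alpha / denom)
    c_t = alpha * v_t / denom

    def eqs(p: np.ndarray) -> list[float]:
        mu, ls, lr = p
        s = float(np.exp(ls))
        rho = float(1.0 / (1.0 + np.exp(-lr)))
        m, v, c = _discretized_moments(mu, s, rho)
        return [m - m_t, v - v_t, c - c_t]

    rho0 = solve_parallel_rho(alpha, k)
    x0 = [m_t, np.log(sd / np.sqrt(k)), np.log(rho0 / (1 - rho0))]
    sol = optimize.root(eqs, x0, method="hybr", tol=1e-12)
    if not sol.success or max(abs(np.array(eqs(sol.x)))) > 1e-8:
        raise RuntimeError(
            f"discretization calibration failed for targets mean={mean}, sd={sd}, "
            f"alpha={alpha}, k={k}: {sol.message}"
        )
    mu, ls, lr = sol.x
    return float(mu), float(np.exp(ls)), float(1.0 / (1.0 + np.exp(-lr)))


_N_HERMITE = 12


@lru_cache(maxsize=64)
def _hermite_coeffs(mean: float, sd: float, alpha: float, k: int) -> tuple[float, ...]:
    """Hermite expansion of the conditional item mean g(z).

    Returns c_1..c_N with ``g(z) = c_0 + sum_n c_n He_n(z)`` in the
    probabilists' convention, ``c_n = E[g(z) He_n(z)] / n!``.
    """
    from math import factorial

    from numpy.polynomial import hermite_e

    mu, s, rho = _calibrate_discretization(mean, sd, alpha, k)
    sz = s * np.sqrt(rho)
    se = s * np.sqrt(max(1.0 - rho, 1e-12))
    cond_mu = mu + sz * _GH_X
    P = norm.cdf((_CUTS[None, :] - cond_mu[:, None]) / se)
    P = np.diff(
        np.concatenate([np.zeros((len(_GH_X), 1)), P, np.ones((len(_GH_X), 1))], axis=1), axis=1
    )
    g = P @ _CODES
    out = []
    for n in range(1, _N_HERMITE + 1):
        basis = np.zeros(n + 1)
        basis[n] = 1.0
        He_n = hermite_e.hermeval(_GH_X, basis)
        out.append(float(_GH_W @ (g * He_n)) / factorial(n))
    return tuple(out)


def _solve_pair_latent(
    coeffs_a: Sequence[float], coeffs_b: Sequence[float], target_cov: float
) -> float:
    """Latent correlation L with sum_n n! c_n^A c_n^B L^n = target_cov."""
    from math import factorial

    w = np.array(
        [factorial(n + 1) * a * b for n, (a, b) in enumerate(zip(coeffs_a, coeffs_b))]
    )

    def f(L: float) -> float:
        return float(w @ np.power(L, np.arange(1, len(w) + 1))) - target_cov

    lo, hi = -0.9999, 0.9999
    if f(lo) * f(hi) > 0:
        raise ValueError(
            f"cross-scale covariance target {target_cov:.4f} is unreachable for any "
            "latent correlation in (-1, 1)"
        )
    return float(optimize.brentq(f, lo, hi, xtol=1e-12))


# ---------------------------------------------------------------------------
# generators


def _rngs(seed: int, n_streams: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n_streams)]


def generate_latent(spec: SyntheticCohortSpec, seed: Optional[int] = None) -> pd.DataFrame:
    """Draw n x 5 latent subscale scores (multivariate normal, Cholesky).

    Columns follow the canonical TV/PS/PAC/PR/HPR order; means and SDs
    match the configured targets and the correlation matrix is the
    disattenuated latent one.
    """
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(spec.latent_correlation())
    Z = rng.standard_normal((spec.n_participants, len(SUBSCALE_CODES))) @ L.T
    data = {}
    for j, code in enumerate(SUBSCALE_CODES):
        t = spec.targets[code]
        data[code] = t.mean + t.sd * Z[:, j]
    out = pd.DataFrame(data)
    out.insert(0, "participant_id", [f"P{i + 1:04d}" for i in range(spec.n_participants)])
    return out


def generate_items(
    latent: pd.DataFrame,
    spec: SyntheticCohortSpec,
    seed: int,
    instrument: Optional[InstrumentSpec] = None,
    visit: str = "baseline",
    missingness: Optional[float] = None,
) -> list[ResponseRecord]:
    """Emit per-item 6-point responses consistent with the latent scores.

    Items are parallel measurements of the (standardized) latent factor
    with moment-matched discretization; reversed-polarity items are
    recorded on the flipped scale (7 - code) so that downstream
    orientation restores them.  MCAR missingness is applied last.
    """
    instrument = instrument or load_instrument()
    missingness = spec.missingness if missingness is None else missingness
    n = len(latent)
    rng = np.random.default_rng(seed)
    columns: dict[str, np.ndarray] = {}
    for sub in instrument.subscales:
        t = spec.targets[sub.code]
        mu, s, rho = _calibrate_discretization(t.mean, t.sd, t.alpha, sub.n_items)
        z = (latent[sub.code].to_numpy(dtype=float) - t.mean) / t.sd
        common = s * np.sqrt(rho) * z
        noise_sd = s * np.sqrt(1.0 - rho)
        for iid in sub.item_ids:
            x = mu + common + noise_sd * rng.standard_normal(n)
            d = np.clip(np.rint(x), 1, 6)
            if instrument.item(iid).polarity is Polarity.reversed:
                d = 7.0 - d
            columns[iid] = d
    mask = rng.random((n, instrument.n_items)) < missingness if missingness > 0 else None
    records = []
    ids = latent["participant_id"].tolist()
    item_ids = instrument.item_ids
    for i in range(n):
        resp: dict[str, Optional[float]] = {}
        for j, iid in enumerate(item_ids):
            if mask is not None and mask[i, j]:
                resp[iid] = None
            else:
                resp[iid] = float(columns[iid][i])
        records.append(ResponseRecord(participant_id=ids[i], visit=visit, responses=resp))
    return records


def _zlatent(latent: pd.DataFrame, spec: SyntheticCohortSpec, code: str) -> np.ndarray:
    t = spec.targets[code]
    return (latent[code].to_numpy(dtype=float) - t.mean) / t.sd


def generate_outcomes(
    latent: pd.DataFrame,
    spec: SyntheticCohortSpec,
    seed: int,
    visit: str = "baseline",
) -> list[CovariateRecord]:
    """Draw binary covariates from logistic models on the latent z-scores.

    IPV risk rises with abuse/control and partner resistance and falls
    with partner support; full disclosure shows the mirror pattern.
    ``modules_received`` is left empty here — module assignment is the
    triage engine's job (see :func:`generate_cohort`).
    """
    rng = np.random.default_rng(seed)
    n = len(latent)

    def _draw(model: OutcomeModel) -> np.ndarray:
        eta = np.full(n, model.intercept, dtype=float)
        for code, b in model.coefficients.items():
            eta += b * _zlatent(latent, spec, code)
        return (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)

    ipv = _draw(spec.ipv_model)
    disclosed = _draw(spec.disclosure_model)
    not_sure = rng.random(n) < 0.5  # among non-disclosers
    lives = rng.random(n) < spec.p_lives_with_partner
    young = rng.random(n) < spec.p_age_le_25
    newp = rng.random(n) < spec.p_new_partner
    out = []
    for i, pid in enumerate(latent["participant_id"]):
        out.append(
            CovariateRecord(
                participant_id=pid,
                visit=visit,
                any_ipv="yes" if ipv[i] else "no",
                full_disclosure="yes" if disclosed[i] else ("not_sure" if not_sure[i] else "no"),
                lives_with_partner="yes" if lives[i] else "no",
                age_le_25="yes" if young[i] else "no",
                new_partner="yes" if newp[i] else "no",
            )
        )
    return out


@dataclass
class SyntheticCohort:
    responses: list[ResponseRecord]
    covariates: list[CovariateRecord]
    latent: pd.DataFrame  # long: participant_id, visit, visit_index, subscale columns
    spec: SyntheticCohortSpec
    seed: int


def generate_cohort(
    spec: SyntheticCohortSpec,
    seed: Optional[int] = None,
    instrument: Optional[InstrumentSpec] = None,
) -> SyntheticCohort:
    """Baseline-only cohort: latent scores, item responses, covariates.

    Modules received are filled in by running the triage engine on the
    scored responses together with the drawn disclosure status.
    """
    from .scoring import score_cohort, score_record
    from .triage import load_benchmarks, triage_visit

    seed = spec.seed if seed is None else seed
    instrument = instrument or load_instrument()
    r_latent, r_items, r_out = _rngs(seed, 3)
    latent = generate_latent(spec, int(r_latent.integers(2**31)))
    responses = generate_items(latent, spec, int(r_items.integers(2**31)), instrument)
    covariates = generate_outcomes(latent, spec, int(r_out.integers(2**31)))

    benchmarks = load_benchmarks()
    cov_by_id = {c.participant_id: c for c in covariates}
    for rec in responses:
        sv = score_record(rec, instrument)
        cov = cov_by_id[rec.participant_id]
        _, rec_triage = triage_visit(sv, benchmarks, disclosure_status=cov.full_disclosure)
        cov.modules_received = list(rec_triage.final_modules)

    lat = latent.copy()
    lat.insert(1, "visit", "baseline")
    lat.insert(2, "visit_index", 0.0)
    return SyntheticCohort(responses, covariates, lat, spec, seed)


def generate_longitudinal(
    spec: SyntheticCohortSpec,
    seed: Optional[int] = None,
    instrument: Optional[InstrumentSpec] = None,
) -> SyntheticCohort:
    """Three-visit cohort (baseline, month 3, month 6).

    The baseline latent score carries the persistent between-participant
    differences; follow-up latent scores add per-subscale visit effects,
    IPV and module-C slope modifiers, and fresh within-participant noise.
    Item responses are regenerated at every visit (fresh measurement
    error), so observed scores fluctuate around the latent trajectory.
    """
    seed = spec.seed if seed is None else seed
    instrument = instrument or load_instrument()
    base = generate_cohort(spec, seed, instrument)
    r_traj, r_items1, r_items2 = _rngs(seed + 1, 3)

    ipv = np.array([c.any_ipv == "yes" for c in base.covariates], dtype=float)
    modc = np.array(["C" in c.modules_received for c in base.covariates], dtype=float)
    eff = spec.longitudinal

    responses = list(base.responses)
    covariates = list(base.covariates)
    latent_frames = [base.latent]
    for visit, t, r_items in (("month3", 1.0, r_items1), ("month6", 2.0, r_items2)):
        lat_t = base.latent[["participant_id", *SUBSCALE_CODES]].copy()
        for code in SUBSCALE_CODES:
            drift = t * (
                eff.visit_effect.get(code, 0.0)
                + eff.visit_x_module_c.get(code, 0.0) * modc
                + eff.visit_x_ipv.get(code, 0.0) * ipv
            )
            sd = eff.residual_sd.get(code, 0.0)
            noise = sd * r_traj.standard_normal(len(lat_t)) if sd > 0 else 0.0
            lat_t[code] = lat_t[code] + drift + noise
        responses.extend(
            generate_items(
                lat_t, spec, int(r_items.integers(2**31)), instrument, visit=visit
            )
        )
        for c in base.covariates:
            covariates.append(
                CovariateRecord(
                    participant_id=c.participant_id,
                    visit=visit,
                    any_ipv=c.any_ipv,
                    full_disclosure=c.full_disclosure,
                    lives_with_partner=c.lives_with_partner,
                    age_le_25=c.age_le_25,
                    new_partner=c.new_partner,
                    modules_received=[],
                )
            )
        lf = lat_t.copy()
        lf.insert(1, "visit", visit)
        lf.insert(2, "visit_index", t)
        latent_frames.append(lf)

    latent = pd.concat(latent_frames, ignore_index=True)
    return SyntheticCohort(responses, covariates, latent, spec, seed)
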