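import numpy as np
import pandas as pd
import pytest

from heartscore.psychometrics import cronbach_alpha, item_matrix, subscale_correlations
from heartscore.scoring import score_cohort
from heartscore.synthetic import (
    PILOT_TARGETS,
    SyntheticCohortSpec,
    generate_cohort,
    generate_items,
    generate_latent,
    generate_longitudinal,
    generate_outcomes,
    solve_parallel_rho,
    spearman_brown,
)


class TestSolveParallelRho:
    def test_published_tv_alpha(self):
        # alpha=0.84, k=13 -> rho = 0.84/2.92
        assert solve_parallel_rho(0.84, 13) == pytest.approx(0.84 / 2.92, abs=1e-12)

    def test_limit_toward_one(self):
        assert solve_parallel_rho(0.9999, 5) == pytest.approx(1.0, abs=1e-3)

    @pytest.mark.parametrize("alpha,k", [(0.54, 5), (0.74, 9), (0.84, 13), (0.3, 2)])
    def test_round_trip_inverse(self, alpha, k):
        assert spearman_brown(solve_parallel_rho(alpha, k), k) == pytest.approx(alpha, abs=1e-12)

    def test_bounds_rejected(self):
        with pytest.raises(ValueError):
            solve_parallel_rho(1.0, 5)
        with pytest.raises(ValueError):
            solve_parallel_rho(0.5, 1)


class TestGenerateLatent:
    def test_pilot_means_at_large_n(self):
        spec = SyntheticCohortSpec(n_participants=10_000)
        lat = generate_latent(spec, seed=1)
        assert lat["PS"].mean() == pytest.approx(49.0, abs=0.5)
        assert lat["PAC"].mean() == pytest.approx(15.3, abs=0.5)
        assert lat["TV"].std() == pytest.approx(12.5, abs=0.5)

    def test_identity_correlation_target_gives_independence(self):
        spec = SyntheticCohortSpec(
            n_participants=10_000, correlation=np.eye(5).tolist()
        )
        lat = generate_latent(spec, seed=2)
        R = lat[["TV", "PS", "PAC", "PR", "HPR"]].corr().to_numpy()
        off = R[~np.eye(5, dtype=bool)]
        assert np.abs(off).max() < 0.03

    def test_same_seed_reproduces_bitwise(self):
        spec = SyntheticCohortSpec(n_participants=200)
        a = generate_latent(spec, seed=3)
        b = generate_latent(spec, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_infeasible_correlation_rejected(self):
        bad = np.eye(5)
        bad[1, 2] = bad[2, 1] = -0.99  # undisattenuatable PS-PAC demand
        with pytest.raises(ValueError, match="unreachable|positive definite"):
            SyntheticCohortSpec(n_participants=10, correlation=bad.tolist())


class TestGenerateItems:
    def test_scores_track_generating_latent(self, instrument):
        spec = SyntheticCohortSpec(n_participants=2_000, missingness=0.0)
        lat = generate_latent(spec, seed=4)
        recs = generate_items(lat, spec, seed=5, instrument=instrument)
        scores = score_cohort(recs, instrument)
        merged = scores.merge(lat, on="participant_id", suffixes=("_obs", "_true"))
        from heartscore.synthetic import _N_ITEMS, _hermite_coeffs

        for code, t in PILOT_TARGETS.items():
            r = np.corrcoef(merged[f"{code}_obs"], merged[f"{code}_true"])[0, 1]
            # the score-factor correlation is bounded by sqrt(reliability);
            # it should match the analytic effective loading k*c1/sd
            k = _N_ITEMS[code]
            loading = k * _hermite_coeffs(t.mean, t.sd, t.alpha, k)[0] / t.sd
            assert r == pytest.approx(loading, abs=0.04)

    def test_pac_alpha_calibrated_at_large_n(self, instrument):
        spec = SyntheticCohortSpec(n_participants=10_000, missingness=0.0)
        lat = generate_latent(spec, seed=6)
        recs = generate_items(lat, spec, seed=7, instrument=instrument)
        X = item_matrix(recs, instrument, "PAC")
        assert cronbach_alpha(X) == pytest.approx(0.74, abs=0.05)

    def test_total_missingness_invalidates_everything(self, instrument):
        spec = SyntheticCohortSpec(n_participants=20, missingness=1.0)
        lat = generate_latent(spec, seed=8)
        recs = generate_items(lat, spec, seed=9, instrument=instrument)
        scores = score_cohort(recs, instrument)
        assert not scores[[f"{c}_valid" for c in ("TV", "PS", "PAC", "PR", "HPR")]].any().any()

    def test_reversed_item_recorded_on_flipped_scale(self, instrument):
        # oriented ps_02 should correlate positively with the other PS
        # items even though its raw recording is flipped
        spec = SyntheticCohortSpec(n_participants=3_000, missingness=0.0)
        lat = generate_latent(spec, seed=10)
        recs = generate_items(lat, spec, seed=11, instrument=instrument)
        raw_ps02 = np.array([r.responses["ps_02"] for r in recs])
        raw_ps01 = np.array([r.responses["ps_01"] for r in recs])
        assert np.corrcoef(raw_ps02, raw_ps01)[0, 1] < 0
        X = item_matrix(recs, instrument, "PS")  # oriented
        assert np.corrcoef(X[:, 1], X[:, 0])[0, 1] > 0


class TestGenerateOutcomes:
    def test_null_coefficients_hit_intercept_prevalence(self):
        from heartscore.synthetic import OutcomeModel

        spec = SyntheticCohortSpec(
            n_participants=10_000,
            ipv_model=OutcomeModel(intercept=-1.0, coefficients={}),
        )
        lat = generate_latent(spec, seed=12)
        cov = generate_outcomes(lat, spec, seed=13)
        prev = np.mean([c.any_ipv == "yes" for c in cov])
        expected = 1 / (1 + np.exp(1.0))
        assert prev == pytest.approx(expected, abs=3 * np.sqrt(expected * (1 - expected) / 10_000))

    def test_ipv_group_has_higher_abuse_scores(self):
        spec = SyntheticCohortSpec(n_participants=5_000)
        lat = generate_latent(spec, seed=14)
        cov = generate_outcomes(lat, spec, seed=15)
        ipv = np.array([c.any_ipv == "yes" for c in cov])
        pac = lat["PAC"].to_numpy()
        assert pac[ipv].mean() > pac[~ipv].mean()
        ps = lat["PS"].to_numpy()
        assert ps[ipv].mean() < ps[~ipv].mean()

    def test_same_seed_identical_outcomes(self):
        spec = SyntheticCohortSpec(n_participants=100)
        lat = generate_latent(spec, seed=16)
        a = generate_outcomes(lat, spec, seed=17)
        b = generate_outcomes(lat, spec, seed=17)
        assert a == b


class TestGenerateCohort:
    def test_flagged_participants_have_riskier_scores(self, instrument):
        # triage-derived module C assignment should mark higher-PAC,
        # lower-PS participants
        spec = SyntheticCohortSpec(n_participants=1_000)
        cohort = generate_cohort(spec, seed=18)
        modc = np.array(["C" in c.modules_received for c in cohort.covariates])
        assert 0 < modc.sum() < len(modc)
        pac = cohort.latent["PAC"].to_numpy()
        ps = cohort.latent["PS"].to_numpy()
        assert pac[modc].mean() > pac[~modc].mean()
        assert ps[modc].mean() < ps[~modc].mean()

    def test_full_determinism(self):
        spec = SyntheticCohortSpec(n_participants=60)
        a = generate_cohort(spec, seed=19)
        b = generate_cohort(spec, seed=19)
        assert a.responses == b.responses
        assert a.covariates == b.covariates
        pd.testing.assert_frame_equal(a.latent, b.latent)


class TestGenerateLongitudinal:
    def test_zero_effects_and_noise_freeze_trajectories(self):
        from heartscore.synthetic import LongitudinalEffects

        zero = {c: 0.0 for c in ("TV", "PS", "PAC", "PR", "HPR")}
        spec = SyntheticCohortSpec(
            n_participants=50,
            longitudinal=LongitudinalEffects(
                visit_effect=zero, visit_x_module_c=zero, visit_x_ipv=zero, residual_sd=zero
            ),
        )
        cohort = generate_longitudinal(spec, seed=20)
        wide = cohort.latent.pivot(index="participant_id", columns="visit", values="PAC")
        assert np.allclose(wide["baseline"], wide["month3"])
        assert np.allclose(wide["baseline"], wide["month6"])

    def test_module_c_slope_sign_recovered_by_growth_model(self, instrument):
        from heartscore.longitudinal import GrowthModelSpec, fit_growth

        spec = SyntheticCohortSpec(n_participants=500, missingness=0.0)
        cohort = generate_longitudinal(spec, seed=21)
        scores = score_cohort(cohort.responses, instrument)
        cov = pd.DataFrame(
            [
                {
                    "participant_id": c.participant_id,
                    "visit": c.visit,
                    "any_ipv": c.any_ipv,
                    "modules_received": "|".join(c.modules_received),
                }
                for c in cohort.covariates
            ]
        )
        fit = fit_growth(scores, cov, GrowthModelSpec(subscale_code="PAC"))
        idx = fit.term_names.index("visit:module_c")
        assert fit.beta[idx] < 0  # IPV-module recipients decline faster

    def test_three_visits_per_participant(self):
        spec = SyntheticCohortSpec(n_participants=30)
        cohort = generate_longitudinal(spec, seed=22)
        visits = pd.Series([r.visit for r in cohort.responses]).value_counts()
        assert visits.to_dict() == {"baseline": 30, "month3": 30, "month6": 30}


@pytest.fixture(scope="module")
def big_cohort(instrument):
    spec = SyntheticCohortSpec(n_participants=10_000, missingness=0.0)
    cohort = generate_cohort(spec, seed=101)
    scores = score_cohort(cohort.responses, instrument)
    return cohort, scores


class TestCalibrationSuite:
    """End-to-end simulator calibration at n=10,000 (one shared cohort)."""

    def test_means_and_sds_within_half_point(self, big_cohort):
        _, scores = big_cohort
        for code, t in PILOT_TARGETS.items():
            assert scores[code].mean() == pytest.approx(t.mean, abs=0.5)
            assert scores[code].std(ddof=1) == pytest.approx(t.sd, abs=0.5)

    def test_alphas_within_five_points(self, big_cohort, instrument):
        cohort, _ = big_cohort
        for code, t in PILOT_TARGETS.items():
            X = item_matrix(cohort.responses, instrument, code)
            assert cronbach_alpha(X) == pytest.approx(t.alpha, abs=0.05)

    def test_pac_ps_correlation_near_published_value(self, big_cohort):
        _, scores = big_cohort
        R = subscale_correlations(scores)
        assert R.loc["PAC", "PS"] == pytest.approx(-0.63, abs=0.05)
        assert R.loc["PAC", "PR"] == pytest.approx(0.52, abs=0.05)

    def test_discretization_attenuates_alpha(self, big_cohort, instrument):
        cohort, _ = big_cohort
        spec = cohort.spec
        # continuous parallel items with the disattenuated latent would
        # show at least the target alpha; the discretized ones never more
        rng = np.random.default_rng(0)
        for code, t in PILOT_TARGETS.items():
            sub = instrument.subscale(code)
            rho = solve_parallel_rho(t.alpha, sub.n_items)
            z = rng.standard_normal(10_000)
            cont = np.sqrt(rho) * z[:, None] + np.sqrt(1 - rho) * rng.standard_normal(
                (10_000, sub.n_items)
            )
            alpha_cont = cronbach_alpha(cont)
            X = item_matrix(cohort.responses, instrument, code)
            assert cronbach_alpha(X) <= alpha_cont + 0.03
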