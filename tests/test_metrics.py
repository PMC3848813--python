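"""Concordance, Royston-Sauerbrei D, NRI and bootstrap SEs."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from casecohort.cohort import Cohort
from casecohort.design import CaseCohortDesign, draw_case_cohort, full_cohort_design
from casecohort.cox import fit_weighted_cox, breslow_baseline, predict_absolute_risk
from casecohort.metrics import (
    KAPPA,
    NoRelevantPairsError,
    harrell_c,
    weighted_c,
    blom_scores,
    royston_d,
    nri_eligibility,
    nri,
    nri_weighted_alternative,
    bootstrap_se,
)

from oracles import brute_force_concordance


def _random_survival(n, seed, tie_fraction=0.0):
    rng = np.random.default_rng(seed)
    lp = np.round(rng.normal(size=n), 1)  # rounding creates predictor ties
    time = rng.exponential(scale=np.exp(-lp))
    if tie_fraction:
        time = np.round(time, 1) + 0.05  # time ties
    event = (rng.uniform(size=n) < 0.6).astype(int)
    return lp, np.maximum(time, 1e-3), event


class TestHarrellC:
    def test_perfect_discrimination(self):
        time = np.array([1.0, 2.0, 3.0, 4.0])
        lp = np.array([4.0, 3.0, 2.0, 1.0])
        event = np.array([1, 1, 1, 1])
        assert harrell_c(lp, time, event).estimate == 1.0

    def test_constant_predictor_is_half(self):
        lp = np.zeros(10)
        time = np.arange(1.0, 11.0)
        event = np.ones(10, int)
        assert harrell_c(lp, time, event).estimate == 0.5

    @pytest.mark.parametrize("seed", [0, 1])
    @pytest.mark.parametrize("tie_fraction", [0.0, 0.3])
    def test_matches_brute_force_enumeration(self, seed, tie_fraction):
        lp, time, event = _random_survival(60, seed, tie_fraction)
        res = harrell_c(lp, time, event)
        est, counts = brute_force_concordance(lp, time, event)
        assert res.estimate == pytest.approx(est, abs=1e-12)
        pc = res.pair_counts
        assert (pc.n_c1, pc.n_d1, pc.n_u1, pc.n_c0, pc.n_d0, pc.n_u0) == counts

    def test_matches_lifelines(self):
        from lifelines.utils import concordance_index

        lp, time, event = _random_survival(150, 5)
        assert harrell_c(lp, time, event).estimate == pytest.approx(
            concordance_index(time, -lp, event), abs=1e-12
        )

    def test_no_relevant_pairs_raises(self):
        with pytest.raises(NoRelevantPairsError):
            harrell_c(np.array([1.0, 2.0]), np.array([1.0, 2.0]), np.array([0, 0]))


class TestWeightedC:
    def test_alpha_one_reduces_to_harrell(self, make_cohort):
        cohort = make_cohort(n=200, seed=50)
        design = full_cohort_design(cohort)
        lp = cohort.covariates @ np.array([0.03, 0.5])
        a = harrell_c(lp, cohort.exit, cohort.event)
        b = weighted_c(lp, design)
        assert b.estimate == a.estimate
        assert b.se == a.se

    def test_four_subject_hand_fixture(self, four_subject_concordance):
        cohort, design = four_subject_concordance
        lp = cohort.covariates[:, 0]
        res = weighted_c(lp, design)
        assert res.estimate == pytest.approx(7.0 / 9.0, abs=1e-12)
        uw = harrell_c(lp, cohort.exit, cohort.event)
        assert uw.estimate == pytest.approx(4.0 / 5.0, abs=1e-12)
        pc = res.pair_counts
        assert (pc.n_c1, pc.n_r1, pc.n_c0, pc.n_d0) == (1, 1, 3, 1)

    def test_matches_brute_force_on_design(self, make_cohort):
        cohort = make_cohort(n=250, seed=51)
        design = draw_case_cohort(cohort, 0.4, seed=7)
        members = design.member_indices()
        rng = np.random.default_rng(8)
        lp = np.round(rng.normal(size=len(cohort)), 1)
        res = weighted_c(lp, design)
        est, _ = brute_force_concordance(
            lp[members], cohort.exit[members], cohort.event[members], alpha=0.4
        )
        assert res.estimate == pytest.approx(est, abs=1e-12)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_weighted_formula_collapses_at_alpha_one(self, seed):
        lp, time, event = _random_survival(40, seed)
        if event.sum() == 0:
            event[0] = 1
        cohort = Cohort(
            ids=np.arange(40), entry=np.zeros(40), exit=time, event=event,
            covariates=lp.reshape(-1, 1), covariate_names=("lp",),
        )
        a = harrell_c(lp, time, event)
        b = weighted_c(lp, full_cohort_design(cohort))
        assert b.estimate == pytest.approx(a.estimate, abs=1e-15)


class TestBlomScores:
    def test_median_rank_is_zero(self):
        z = blom_scores(np.arange(1, 8), 7)
        assert z[3] == pytest.approx(0.0, abs=1e-15)

    def test_closed_form_n5(self):
        from scipy.stats import norm

        probs = (np.arange(1, 6) - 0.375) / 5.25
        expected = norm.ppf(probs) * KAPPA
        np.testing.assert_allclose(blom_scores(np.arange(1, 6), 5), expected)
        # spot value: (1 - 3/8) / (5 + 1/4) = 0.119
        assert probs[0] == pytest.approx(0.119, abs=5e-4)

    def test_half_means_are_plus_minus_half(self):
        z = blom_scores(np.arange(1, 10_001), 10_000)
        assert z[z > 0].mean() == pytest.approx(0.5, abs=5e-3)
        assert z[z < 0].mean() == pytest.approx(-0.5, abs=5e-3)

    def test_rank_beyond_effective_n_rejected(self):
        with pytest.raises(ValueError, match="effective"):
            blom_scores(np.array([1.0, 12.0]), 10)


class TestRoystonD:
    def test_alpha_one_equals_full_cohort_d(self, make_cohort):
        cohort = make_cohort(n=300, seed=52)
        lp = cohort.covariates @ np.array([0.03, 0.5])
        full = royston_d(lp, cohort)
        reduced = royston_d(lp, full_cohort_design(cohort))
        assert reduced.estimate == full.estimate
        assert reduced.se == full.se

    def test_normal_lp_limit(self):
        # for lp ~ N(0, sigma^2) truly proportional to the log hazard and
        # light censoring, D ~ sqrt(8/pi) * sigma
        rng = np.random.default_rng(53)
        n, sigma = 6000, 0.8
        lp = rng.normal(0, sigma, size=n)
        time = rng.exponential(scale=np.exp(-lp))
        admin = np.quantile(time, 0.95)
        event = (time <= admin).astype(int)
        cohort = Cohort(
            ids=np.arange(n), entry=np.zeros(n), exit=np.minimum(time, admin),
            event=event, covariates=lp.reshape(-1, 1), covariate_names=("lp",),
        )
        d = royston_d(lp, cohort)
        assert d.estimate == pytest.approx(np.sqrt(8 / np.pi) * sigma, rel=0.05)

    def test_constant_predictor_degenerate(self, make_cohort):
        cohort = make_cohort(n=100, seed=54)
        d = royston_d(np.zeros(len(cohort)), cohort)
        assert d.estimate == 0.0
        assert d.degenerate

    def test_weighted_ranks_upweight_controls(self, make_cohort):
        # the effective n of the weighted ranks approximates the full cohort
        cohort = make_cohort(n=1000, seed=55)
        design = draw_case_cohort(cohort, 0.2, seed=9)
        members = design.member_indices()
        controls = (cohort.event[members] == 0).sum()
        cases = (cohort.event[members] == 1).sum()
        expected_total = cases + controls / 0.2
        from casecohort.metrics import _weighted_ranks

        lp = np.arange(len(members), dtype=float)
        _, total = _weighted_ranks(lp, np.where(cohort.event[members] == 0, 5.0, 1.0))
        assert total == pytest.approx(expected_total)
        assert total == pytest.approx(len(cohort), rel=0.25)


class TestNriEligibility:
    def _design(self):
        # ids: 0 event@5 (sub), 1 event@12 outside sub, 2 event@12 in sub,
        # 3 censored@8 (sub), 4 censored@15 (sub)
        cohort = Cohort(
            ids=np.arange(5),
            entry=np.zeros(5),
            exit=np.array([5.0, 12.0, 12.0, 8.0, 15.0]),
            event=np.array([1, 1, 1, 0, 0]),
            covariates=np.zeros((5, 1)),
            covariate_names=("x",),
        )
        flags = np.array([True, False, True, True, True])
        return CaseCohortDesign(cohort=cohort, alpha=0.8, in_subcohort=flags)

    def test_late_nonsubcohort_case_excluded_subcohort_case_kept(self):
        elig = nri_eligibility(self._design(), t=10.0)
        assert 1 not in elig.indices  # late case outside the subcohort
        assert 2 in elig.indices  # same event time, inside: a non-event
        assert not elig.is_event[list(elig.indices).index(2)]
        assert elig.excluded_late_cases == 1

    def test_early_censoring_excluded(self):
        elig = nri_eligibility(self._design(), t=10.0)
        assert 3 not in elig.indices
        assert elig.excluded_censored == 1

    def test_full_cohort_only_excludes_early_censored(self, make_cohort):
        cohort = make_cohort(n=500, seed=60)
        elig = nri_eligibility(full_cohort_design(cohort), t=10.0)
        assert elig.excluded_late_cases == 0
        n_censored_early = np.sum((cohort.event == 0) & (cohort.exit <= 10.0))
        assert elig.excluded_censored == n_censored_early


class TestNri:
    def _elig(self, n_events, n_nonevents):
        from casecohort.metrics import NriEligibility

        idx = np.arange(n_events + n_nonevents)
        return NriEligibility(
            indices=idx,
            is_event=np.concatenate([np.ones(n_events, bool), np.zeros(n_nonevents, bool)]),
            is_late_case=np.zeros(n_events + n_nonevents, bool),
            excluded_late_cases=0,
            excluded_censored=0,
            horizon=10.0,
        )

    def test_identical_risks_give_zero(self):
        elig = self._elig(5, 10)
        risks = np.linspace(0.01, 0.4, 15)
        res = nri(risks, risks, elig, mode="categories")
        assert res.nri == 0.0 and res.nri_events == 0.0 and res.nri_nonevents == 0.0

    def test_hand_counts(self):
        # 10 events: 3 up, 1 down; 20 non-events: 2 down, 4 up -> NRI = 0.1
        elig = self._elig(10, 20)
        old = np.full(30, 0.15)
        new = old.copy()
        new[:3] = 0.25          # events up
        new[3] = 0.05           # event down
        new[10:12] = 0.05       # non-events down
        new[12:16] = 0.25       # non-events up
        res = nri(old, new, elig, mode="categories", boundaries=(0.10, 0.20))
        assert res.nri == pytest.approx(0.1, abs=1e-15)
        assert res.nri_events == pytest.approx(0.2)
        assert res.nri_nonevents == pytest.approx(-0.1)
        assert (res.events_up, res.events_down) == (3, 1)
        assert (res.nonevents_up, res.nonevents_down) == (4, 2)

    def test_boundary_risk_falls_in_upper_category(self):
        elig = self._elig(1, 1)
        old = np.array([0.09, 0.09])
        new = np.array([0.10, 0.10])  # exactly on the 10% boundary -> "up"
        res = nri(old, new, elig, mode="categories", boundaries=(0.10, 0.20))
        assert res.events_up == 1 and res.nonevents_up == 1

    def test_continuous_counts_any_change(self):
        elig = self._elig(2, 2)
        old = np.array([0.10, 0.10, 0.10, 0.10])
        new = np.array([0.100001, 0.10, 0.099999, 0.10])
        res = nri(old, new, elig, mode="continuous")
        assert res.nri_events == pytest.approx(0.5)
        assert res.nri_nonevents == pytest.approx(0.5)

    def test_decomposition_identity(self):
        rng = np.random.default_rng(61)
        n = 500
        elig = self._elig(100, 400)
        old = rng.uniform(0, 0.5, n)
        new = np.clip(old + rng.normal(0, 0.05, n), 0, 1)
        for mode in ("categories", "continuous"):
            res = nri(old, new, elig, mode=mode)
            assert res.nri == res.nri_events + res.nri_nonevents
            assert -2.0 <= res.nri <= 2.0

    def test_empty_group_raises_naming_it(self):
        elig = self._elig(0, 5)
        risks = np.full(5, 0.1)
        with pytest.raises(ValueError, match="events"):
            nri(risks, risks + 0.01, elig)

    def test_event_side_identical_between_designs(self, make_cohort):
        # with identical risk inputs the event portion does not depend on
        # the design: events by the horizon are the same subjects
        cohort = make_cohort(n=800, seed=62)
        rng = np.random.default_rng(63)
        old = rng.uniform(0, 0.5, len(cohort))
        new = np.clip(old + rng.normal(0, 0.08, len(cohort)), 0, 1)
        full_res = nri(old, new, nri_eligibility(full_cohort_design(cohort), 10.0))
        design = draw_case_cohort(cohort, 0.3, seed=64)
        cc_res = nri(old, new, nri_eligibility(design, 10.0))
        assert cc_res.nri_events == pytest.approx(full_res.nri_events, abs=1e-15)


class TestNriWeightedAlternative:
    def test_alpha_one_equals_standard(self, make_cohort):
        cohort = make_cohort(n=600, seed=65)
        rng = np.random.default_rng(66)
        old = rng.uniform(0, 0.5, len(cohort))
        new = np.clip(old + rng.normal(0, 0.05, len(cohort)), 0, 1)
        design = full_cohort_design(cohort)
        std = nri(old, new, nri_eligibility(design, 10.0))
        alt = nri_weighted_alternative(old, new, design, 10.0)
        assert alt.nri == pytest.approx(std.nri, abs=1e-15)
        assert alt.nri_nonevents == pytest.approx(std.nri_nonevents, abs=1e-15)

    def test_hand_weighted_nonevent_portion(self):
        # one up-moving control (weight 1/0.5 = 2), one static late case
        # (weight 1), one event moving up
        cohort = Cohort(
            ids=np.arange(3),
            entry=np.zeros(3),
            exit=np.array([5.0, 15.0, 20.0]),
            event=np.array([1, 1, 0]),
            covariates=np.zeros((3, 1)),
            covariate_names=("x",),
        )
        design = CaseCohortDesign(
            cohort=cohort, alpha=0.5, in_subcohort=np.array([True, False, True])
        )
        old = np.array([0.15, 0.15, 0.05])
        new = np.array([0.25, 0.15, 0.15])  # event up; late case static; control up
        res = nri_weighted_alternative(old, new, design, t=10.0, mode="categories")
        assert res.nri_events == pytest.approx(1.0)
        # weighted non-event portion: (down - up)/total = (0 - 2)/(1 + 2)
        assert res.nri_nonevents == pytest.approx(-2.0 / 3.0)
        assert res.excluded_late_cases == 0


class TestExport:
    def test_structured_text_records_round_trip(self, four_subject_concordance, tmp_path):
        import pandas as pd
        from casecohort.metrics import export_results

        cohort, design = four_subject_concordance
        lp = cohort.covariates[:, 0]
        results = [harrell_c(lp, cohort.exit, cohort.event), weighted_c(lp, design)]
        path = tmp_path / "metrics.csv"
        export_results(results, path)
        back = pd.read_csv(path)
        assert list(back["metric"]) == ["c", "c_w"]
        assert back["estimate"].iloc[1] == pytest.approx(7 / 9)
        assert back["alpha"].iloc[1] == 0.5


class TestBootstrap:
    def test_constant_metric_has_zero_se(self, make_cohort):
        cohort = make_cohort(n=200, seed=70)
        design = draw_case_cohort(cohort, 0.5, seed=71)
        assert bootstrap_se(lambda d: 1.23, design, B=60, seed=0) == pytest.approx(0.0, abs=1e-12)

    def test_requires_minimum_replicates(self, make_cohort):
        design = draw_case_cohort(make_cohort(n=100, seed=72), 0.5, seed=0)
        with pytest.raises(ValueError, match="B"):
            bootstrap_se(lambda d: 1.0, design, B=10, seed=0)

    def test_deterministic_given_seed(self, make_cohort):
        cohort = make_cohort(n=300, seed=73)
        design = draw_case_cohort(cohort, 0.4, seed=74)

        def metric(d):
            fit = fit_weighted_cox(d, scheme="prentice")
            return float(fit.betas[0])

        a = bootstrap_se(metric, design, B=50, seed=5)
        b = bootstrap_se(metric, design, B=50, seed=5)
        assert a == b and a > 0

    def test_weighted_c_bootstrap_tracks_design_variability(self, small_spec, small_model):
        # bootstrap SE of the weighted C on one design vs the empirical SD
        # over 200 independent outcome realisations and subcohort draws
        from casecohort.simulate import generate_covariates, simulate_cohort

        x = generate_covariates(600, small_spec, seed=75)
        betas = np.array(small_model.betas)

        def metric(d):
            return weighted_c(d.cohort.covariates @ betas, d).estimate

        values = []
        for s in range(200):
            cohort = simulate_cohort(x, small_model, seed=500 + s, covariate_names=small_spec.names)
            values.append(metric(draw_case_cohort(cohort, 0.3, seed=9000 + s)))
        cohort = simulate_cohort(x, small_model, seed=500, covariate_names=small_spec.names)
        design = draw_case_cohort(cohort, 0.3, seed=9000)
        boot = bootstrap_se(metric, design, B=200, seed=1)
        ratio = boot / np.std(values, ddof=1)
        assert 0.8 < ratio < 1.2
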