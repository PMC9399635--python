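"""Transition engine, cohort microsimulation, and the matrix oracle."""

import numpy as np
import pytest

from gcrss._rng import CounterRng
from gcrss.model_params import HealthState, RiskProfile
from gcrss.natural_history import (
    Individual,
    advance_cycle,
    annual_transition_probabilities,
    build_arrays,
    cohort_matrix_oracle,
    simulate_cohort,
    stratum_index,
)

S = HealthState


def _person(state=S.Normal, age=30, hp=True, smoking="never", **kw):
    return Individual(id=0, age=age, profile=RiskProfile("male", hp, smoking),
                      state=state, **kw)


class TestTransitionProbabilities:
    def test_hp_multiplier_is_exact_ratio(self, ps, lt):
        pos = annual_transition_probabilities(_person(S.NonAtrophicGastritis, hp=True), ps, lt)
        neg = annual_transition_probabilities(_person(S.NonAtrophicGastritis, hp=False), ps, lt)
        ratio = pos[S.AtrophicGastritis] / neg[S.AtrophicGastritis]
        assert ratio == pytest.approx(ps.value("rr_hp_atrophy"))

    def test_smoking_multiplier_on_dysplasia_progression(self, ps, lt):
        hv = annual_transition_probabilities(_person(S.IntestinalMetaplasia, smoking="heavy"), ps, lt)
        nv = annual_transition_probabilities(_person(S.IntestinalMetaplasia, smoking="never"), ps, lt)
        assert hv[S.Dysplasia] / nv[S.Dysplasia] == pytest.approx(
            ps.value("rr_smoking_heavy"))

    def test_dead_individual_rejected(self, ps, lt):
        dead = _person(S.DeathOther)
        with pytest.raises(ValueError):
            annual_transition_probabilities(dead, ps, lt)
        with pytest.raises(ValueError):
            advance_cycle(dead, ps, lt, CounterRng(0, 0))

    def test_rows_sum_to_one_for_random_individuals(self, arrays):
        rng = np.random.default_rng(0)
        ages = rng.integers(0, 81, 1000)
        strata = rng.integers(0, 36, 1000)
        states = rng.integers(0, 15, 1000)
        rows = arrays.M[ages, strata, states]
        assert np.allclose(rows.sum(axis=1), 1.0, atol=1e-12)
        assert rows.min() >= 0.0


class TestAdvanceCycle:
    def test_forced_gc_death(self, ps, lt):
        forced = ps.with_overrides({"gc_mortality_4": 1.0})
        ind = _person(S.ClinicalGC_IV, age=40)
        advance_cycle(ind, forced, lt, CounterRng(1, 0))
        # background death may pre-empt, but with this table q(40) << 1
        assert ind.state == S.DeathGC
        assert ind.cause_of_death == "gc"
        assert ind.tallies["life_years"] == 0.5

    def test_identity_dynamics_accrues_one_life_year(self, ps, lt):
        frozen = ps.with_overrides({k: 0.0 for k in (
            "p_normal_nag", "p_nag_ag", "p_ag_im", "p_im_dys", "p_dys_pre1")})
        # null background mortality via a zero life table
        zlt = type(lt)(np.zeros(101), np.zeros(101))
        ind = _person(S.Normal, age=30)
        advance_cycle(ind, frozen, zlt, CounterRng(1, 0))
        assert ind.state == S.Normal
        assert ind.age == 31
        assert ind.tallies["life_years"] == 1.0
        assert ind.years_in_state == 1

    def test_rng_is_required(self, ps, lt):
        with pytest.raises(ValueError):
            advance_cycle(_person(), ps, lt, None)


class TestSimulateCohort:
    def test_bit_identical_reruns(self, ps, lt, arrays):
        a, _ = simulate_cohort(1000, None, ps, lt, 11, arrays=arrays)
        b, _ = simulate_cohort(1000, None, ps, lt, 11, arrays=arrays)
        assert a == b
        c, _ = simulate_cohort(1000, None, ps, lt, 12, arrays=arrays)
        assert c != a

    def test_death_conservation_and_cause_partition(self, ps, lt, arrays):
        res, _ = simulate_cohort(5000, 40, ps, lt, 2, arrays=arrays)
        total_deaths = (res.gc_deaths + res.other_deaths
                        + res.complication_deaths)
        assert total_deaths == res.n
        assert res.surgery_deaths <= res.complication_deaths
        assert sum(res.stage_counts) == res.gc_cases

    def test_invalid_inputs(self, ps, lt):
        with pytest.raises(ValueError):
            simulate_cohort(0, None, ps, lt, 1)
        with pytest.raises(ValueError):
            simulate_cohort(10, 41, ps, lt, 1)

    def test_lifetime_incidence_near_calibrated_level(self, ps, lt, arrays):
        res, _ = simulate_cohort(100_000, None, ps, lt, 5, arrays=arrays)
        # plausibility band around the 11.6% emulated lifetime incidence
        assert res.gc_cases / res.n == pytest.approx(0.116, abs=0.012)

    def test_risk_free_profile_has_fewer_cases(self, ps, lt, arrays):
        base, _ = simulate_cohort(30_000, None, ps, lt, 3, arrays=arrays)
        clean, _ = simulate_cohort(
            30_000, None, ps, lt, 3,
            profile_override={"hp": False, "smoking": "never"}, arrays=arrays)
        assert clean.gc_cases < base.gc_cases

    def test_event_log_is_chronological_per_individual(self, ps, lt, arrays):
        _, log = simulate_cohort(200, 40, ps, lt, 4, log_events=True, arrays=arrays)
        df = log.to_dataframe()
        assert len(df) > 0
        assert (df.groupby("id").age.apply(lambda s: (s.diff().dropna() >= 0).all())).all()


class TestMatrixOracle:
    def test_rejects_screening_strategy(self, ps, lt):
        with pytest.raises(ValueError):
            cohort_matrix_oracle(ps, lt, strategy=40)

    def test_occupancy_conservation(self, ps, lt, arrays):
        o = cohort_matrix_oracle(ps, lt, arrays=arrays)
        assert np.allclose(o.occupancy.sum(axis=1), 1.0, atol=1e-9)

    def test_zero_progression_reduces_to_life_table(self, ps, lt):
        frozen = ps.with_overrides({"p_normal_nag": 0.0})
        o = cohort_matrix_oracle(frozen, lt)
        assert o.lifetime_incidence == 0.0
        assert o.gc_deaths == 0.0
        assert o.life_years == pytest.approx(lt.expectation_from(20), abs=1e-9)

    def test_microsimulation_agrees_within_monte_carlo_error(self, ps, lt, arrays):
        n = 200_000
        o = cohort_matrix_oracle(ps, lt, arrays=arrays)
        res, _ = simulate_cohort(n, None, ps, lt, 7, arrays=arrays)
        p = o.gc_deaths
        se = np.sqrt(p * (1 - p) / n) * 1e5
        assert abs(res.gc_deaths / n * 1e5 - p * 1e5) <= 3 * se
        # life-years: conservative per-person sd bound of 12 years
        assert abs(res.life_years - o.life_years) <= 3 * 12 / np.sqrt(n)

    def test_raising_progression_raises_gc_deaths(self, ps, lt):
        base = cohort_matrix_oracle(ps, lt).gc_deaths
        for name in ("p_normal_nag", "p_im_dys", "p_dys_pre1"):
            up = cohort_matrix_oracle(
                ps.with_overrides({name: ps.value(name) * 1.2}), lt).gc_deaths
            assert up > base, name

    def test_stratum_index_is_bijective(self):
        seen = set()
        for sex in (0, 1):
            for hp in (0, 1):
                for smoke in (0, 1, 2):
                    for treat in (0, 1, 2):
                        seen.add(int(stratum_index(sex, hp, smoke, treat)))
        assert seen == set(range(36))
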