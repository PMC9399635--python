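"""GCRSS protocol: stratification, testing, treatment, scheduling."""

import numpy as np
import pytest

from gcrss._rng import CounterRng
from gcrss.model_params import HealthState, RiskProfile
from gcrss.natural_history import Individual, build_arrays, simulate_cohort
from gcrss.screening import (
    ScreeningPolicy,
    SerologyResult,
    classify_risk_level,
    eradicate_hp,
    perform_endoscopy,
    perform_serology,
    run_policy_for_year,
)

S = HealthState


def _person(state=S.Normal, age=40, hp=True, smoking="never", level="unassigned"):
    ind = Individual(id=0, age=age, profile=RiskProfile("male", hp, smoking),
                     state=state)
    ind.screening_level = level
    return ind


@pytest.mark.parametrize("hp,atrophy,expected", [
    (False, False, "A"), (True, False, "B"), (True, True, "C"), (False, True, "D"),
])
def test_risk_level_truth_table(hp, atrophy, expected):
    assert classify_risk_level(SerologyResult(hp, atrophy)) == expected


class TestSerology:
    def test_perfect_assay_reports_truth(self, ps, lt):
        perfect = ps.with_overrides({
            "sens_hp_serology": 1.0, "spec_hp_serology": 1.0,
            "sens_atrophy_serology": 1.0, "spec_atrophy_serology": 1.0})
        res = perform_serology(_person(S.Normal, hp=True), perfect, CounterRng(1, 0))
        assert res == SerologyResult(True, False)
        res = perform_serology(_person(S.Dysplasia, hp=False), perfect, CounterRng(1, 0))
        assert res == SerologyResult(False, True)

    def test_sensitivity_recovered_binomially(self, ps):
        sens = ps.value("sens_hp_serology")
        n = 10_000
        hits = sum(
            perform_serology(
                Individual(id=i, age=40, profile=RiskProfile("male", True, "never")),
                ps, CounterRng(3, i)).hp_positive
            for i in range(n))
        se = np.sqrt(sens * (1 - sens) / n)
        assert abs(hits / n - sens) <= 3 * se

    def test_dead_individual_rejected(self, ps):
        with pytest.raises(ValueError):
            perform_serology(_person(S.DeathOther), ps, CounterRng(0, 0))


class TestEradication:
    def test_forced_success_clears_infection(self, ps):
        ind = _person(hp=True, level="B")
        eradicate_hp(ind, ps.with_overrides({"hp_eradication_success": 1.0}),
                     CounterRng(1, 0))
        assert not ind.profile.hp_infected
        assert ind.treated_flags["hp_eradicated"]

    @pytest.mark.parametrize("level", ["A", "D"])
    def test_levels_a_and_d_never_treated(self, ps, level):
        with pytest.raises(ValueError):
            eradicate_hp(_person(level=level), ps, CounterRng(1, 0))

    def test_false_positive_costs_without_effect(self, ps):
        ind = _person(hp=False, level="C")
        eradicate_hp(ind, ps, CounterRng(1, 0))
        assert not ind.profile.hp_infected
        assert not ind.treated_flags["hp_eradicated"]
        assert ind.tallies["cost"]["hp_therapy"] > 0


class TestEndoscopy:
    def test_true_negative_on_normal_mucosa(self, ps):
        perfect = ps.with_overrides({"spec_endoscopy": 1.0})
        out = perform_endoscopy(_person(S.Normal), perfect, CounterRng(1, 0))
        assert out.finding == "negative"
        assert out.treatment_given == "none"

    def test_detected_dysplasia_sets_treatment_flag(self, ps, lt):
        certain = ps.with_overrides({
            "sens_endo_dysplasia": 1.0, "esd_fraction_dysplasia": 1.0,
            "p_bleeding_esd": 0.0, "p_perforation_esd": 0.0})
        ind = _person(S.Dysplasia)
        out = perform_endoscopy(ind, certain, CounterRng(1, 0))
        assert out.finding == "dysplasia" and out.treatment_given == "esd"
        assert ind.treated_flags["post_esd"]
        # progression out of dysplasia now reduced by the post-ESD RR
        from gcrss.natural_history import annual_transition_probabilities
        treated = annual_transition_probabilities(ind, certain, lt)
        untreated = annual_transition_probabilities(_person(S.Dysplasia), certain, lt)
        assert treated[S.PreclinicalGC_I] / untreated[S.PreclinicalGC_I] == \
            pytest.approx(certain.value("rr_progression_after_esd"))

    def test_screen_detected_stage_two_becomes_clinical(self, ps):
        certain = ps.with_overrides({"sens_endo_pre2": 1.0})
        ind = _person(S.PreclinicalGC_II)
        out = perform_endoscopy(ind, certain, CounterRng(1, 0))
        assert out.finding == "GC stage II"
        assert ind.state == S.ClinicalGC_II

    def test_surgery_death_rate_binomial(self, ps):
        surgical = ps.with_overrides({
            "sens_endo_dysplasia": 1.0, "esd_fraction_dysplasia": 0.0,
            "p_bleeding_surgery": 0.0, "p_perforation_surgery": 0.0})
        p = surgical.value("p_surgery_death")
        n = 10_000
        deaths = 0
        for i in range(n):
            ind = Individual(id=i, age=40, profile=RiskProfile("male", True, "never"),
                             state=S.Dysplasia)
            deaths += perform_endoscopy(ind, surgical, CounterRng(5, i)).death
        se = np.sqrt(p * (1 - p) / n)
        assert abs(deaths / n - p) <= 3 * se


class TestPolicyScheduling:
    def test_policy_inactive_before_start_age(self, ps, lt):
        ind = _person(age=35)
        run_policy_for_year(ind, ScreeningPolicy(40), ps, CounterRng(1, 0))
        assert ind.tallies["serology_tests"] == 0
        assert ind.tallies["disc_cost"] == 0.0

    def test_level_a_retests_in_five_years(self, ps):
        clean = ps.with_overrides({"spec_hp_serology": 1.0, "spec_atrophy_serology": 1.0})
        ind = _person(age=40, hp=False)
        run_policy_for_year(ind, ScreeningPolicy(40), clean, CounterRng(1, 0))
        assert ind.screening_level == "A"
        assert ind.next_screen_due == 45

    def test_level_c_biennial_endoscopies(self, ps):
        certain = ps.with_overrides({
            "sens_hp_serology": 1.0, "sens_atrophy_serology": 1.0,
            "hp_eradication_success": 0.0})
        ind = _person(S.AtrophicGastritis, age=40, hp=True)
        pol = ScreeningPolicy(40)
        run_policy_for_year(ind, pol, certain, CounterRng(1, 0))
        assert ind.screening_level == "C"
        assert ind.next_screen_due == 42
        endoscopy_ages = []
        for age in range(41, 47):
            ind.age = age
            before = ind.tallies["endoscopies"]
            run_policy_for_year(ind, pol, certain, CounterRng(1, 0))
            if ind.tallies["endoscopies"] > before:
                endoscopy_ages.append(age)
        assert endoscopy_ages == [42, 44, 46]

    def test_invalid_start_age_rejected(self):
        with pytest.raises(ValueError):
            ScreeningPolicy(42)
        with pytest.raises(ValueError):
            ScreeningPolicy(40, {"A": 0, "B": 3, "C": 2, "D": 1})


class TestCohortLevelProperties:
    def test_screening_averts_deaths_under_perfect_safe_tests(self, ps, lt):
        safe = ps.with_overrides({
            "sens_hp_serology": 1.0, "spec_hp_serology": 1.0,
            "sens_atrophy_serology": 1.0, "spec_atrophy_serology": 1.0,
            "sens_endo_dysplasia": 1.0, "sens_endo_pre1": 1.0,
            "sens_endo_pre2": 1.0, "sens_endo_pre3": 1.0, "sens_endo_pre4": 1.0,
            "spec_endoscopy": 1.0, "p_bleeding_esd": 0.0, "p_perforation_esd": 0.0,
            "p_bleeding_surgery": 0.0, "p_perforation_surgery": 0.0,
            "p_surgery_death": 0.0})
        arr = build_arrays(safe, lt)
        ref, _ = simulate_cohort(20_000, None, safe, lt, 9, arrays=arr)
        for start in (40, 55, 70):
            res, _ = simulate_cohort(20_000, start, safe, lt, 9, arrays=arr)
            assert res.gc_deaths <= ref.gc_deaths, start
            assert res.complication_deaths == 0

    def test_zero_sensitivity_makes_screening_inert(self, ps, lt):
        blind = ps.with_overrides({
            "sens_hp_serology": 0.0, "sens_atrophy_serology": 0.0,
            "sens_endo_dysplasia": 0.0, "sens_endo_pre1": 0.0,
            "sens_endo_pre2": 0.0, "sens_endo_pre3": 0.0, "sens_endo_pre4": 0.0,
            "spec_hp_serology": 1.0, "spec_atrophy_serology": 1.0})
        arr = build_arrays(blind, lt)
        ref, _ = simulate_cohort(10_000, None, blind, lt, 13, arrays=arr)
        res, _ = simulate_cohort(10_000, 40, blind, lt, 13, arrays=arr)
        assert res.gc_cases == ref.gc_cases
        assert res.gc_deaths == ref.gc_deaths
        assert res.life_years == ref.life_years
        assert res.disc_cost > ref.disc_cost  # serology still billed

    def test_endoscopy_audit_identity(self, ps, lt, arrays):
        # total endoscopies recorded equal the event-log count
        res, log = simulate_cohort(2_000, 40, ps, lt, 21, log_events=True,
                                   arrays=arrays)
        df = log.to_dataframe()
        assert res.serology_tests == (df.event.str.startswith("serology")).sum()
        assert res.endoscopies == (df.event == "endoscopy").sum()

    def test_later_start_weakly_fewer_endoscopies_and_deaths_averted(self, ps, lt, arrays):
        ref, _ = simulate_cohort(20_000, None, ps, lt, 17, arrays=arrays)
        prev_endo, prev_averted = np.inf, np.inf
        for start in (40, 45, 50, 55, 60, 65, 70):
            res, _ = simulate_cohort(20_000, start, ps, lt, 17, arrays=arrays)
            averted = ref.gc_deaths - res.gc_deaths
            assert res.endoscopies <= prev_endo
            assert averted <= prev_averted
            prev_endo, prev_averted = res.endoscopies, averted
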