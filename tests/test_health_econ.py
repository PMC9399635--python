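"""Benefit/harm arithmetic, ICERs, frontier and WTP classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gcrss.health_econ import (
    comparative_metrics,
    compute_icer,
    discount_factor,
    efficiency_frontier,
    wtp_classify,
)

from conftest import REFERENCE_DERIVED, REFERENCE_TABLE


class TestDiscounting:
    def test_anchor_year(self):
        assert discount_factor(20, 0.05) == 1.0

    def test_one_year(self):
        assert discount_factor(21, 0.05) == pytest.approx(1 / 1.05, rel=1e-12)

    def test_matches_iterated_division(self):
        v = 1.0
        for _ in range(20):
            v /= 1.05
        assert discount_factor(40, 0.05) == pytest.approx(v, rel=1e-12)

    def test_pre_entry_age_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(19, 0.05)


class TestComparativeMetrics:
    @pytest.mark.parametrize("label", list(REFERENCE_DERIVED))
    def test_reference_table_derived_cells(self, table_results, label):
        """All derived cells of the published strategy table come back
        exactly from its primary cells under the reporting rounding."""
        m = comparative_metrics(table_results[label], table_results["no screening"])
        rep = m.report()
        exp = REFERENCE_DERIVED[label]
        assert m.deaths_averted == REFERENCE_TABLE[label]["averted"]
        assert rep["net_deaths_averted"] == exp["net"]
        assert rep["nns"] == exp["nns"]
        assert rep["endoscopies_per_death_averted"] == exp["epda"]
        assert rep["endoscopies_per_life_year_gained"] in exp["eplyg"]
        assert rep["life_years_gained_per_death_averted"] == exp["lypda"]
        assert rep["benefit_to_harm_ratio"] == REFERENCE_TABLE[label]["b2h"]

    def test_harm_free_limit(self, table_results):
        res = table_results["40-GCRSS"]
        res = type(res)(**{**res.__dict__, "complication_events": 0,
                           "complication_deaths": 0})
        m = comparative_metrics(res, table_results["no screening"])
        assert m.benefit_to_harm_ratio == 0.0
        assert m.net_deaths_averted == m.deaths_averted

    def test_no_deaths_averted_is_flagged_nan(self, table_results):
        ref = table_results["no screening"]
        m = comparative_metrics(ref, ref)
        assert np.isnan(m.nns) and np.isnan(m.benefit_to_harm_ratio)

    def test_unequal_n_rejected(self, table_results):
        bad = type(table_results["40-GCRSS"])(
            **{**table_results["40-GCRSS"].__dict__, "n": 50_000})
        with pytest.raises(ValueError):
            comparative_metrics(bad, table_results["no screening"])


class TestIcer:
    def test_published_pair(self):
        icer = compute_icer(960.3, 19.361, 103.6, 19.293)
        assert icer == pytest.approx(856.7 / 0.068, rel=1e-9)
        assert icer == pytest.approx(12601, rel=0.001)

    def test_dominance_verdicts(self):
        assert compute_icer(10.0, 1.0, 5.0, 1.0) == "dominated"
        assert compute_icer(5.0, 2.0, 10.0, 1.0) == "dominant"
        with pytest.raises(ValueError):
            compute_icer(1.0, 1.0, 1.0, 1.0)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(0, 1e4), st.floats(0, 100),
           st.floats(1, 1e3), st.floats(0.01, 10))
    def test_translation_invariance(self, x, y, dc, dq):
        a = compute_icer(x + dc, y + dq, x, y)
        b = compute_icer(dc, dq, 0.0, 0.0)
        assert a == pytest.approx(b, rel=1e-6)


def _brute_force_frontier(points):
    """Independent gift-wrapping hull oracle on (qaly, cost) pairs."""
    live = [p for p in points
            if not any(q[1] <= p[1] and q[2] >= p[2] and q[1:] != p[1:]
                       for q in points)]
    cur = min(live, key=lambda p: (p[1], -p[2]))
    frontier = [cur[0]]
    while True:
        cands = [p for p in live if p[2] > cur[2]]
        if not cands:
            return frontier
        cur = min(cands, key=lambda p: ((p[1] - cur[1]) / (p[2] - cur[2]), -p[2]))
        frontier.append(cur[0])


class TestFrontier:
    def test_published_cost_qaly_pairs(self, table_results):
        table = efficiency_frontier(
            [(r.strategy, r.disc_cost, r.disc_qaly) for r in table_results.values()])
        front = set(table[table.on_frontier].strategy)
        assert front == {"no screening", "55-GCRSS", "45-GCRSS", "40-GCRSS"}
        flagged = table[~table.on_frontier]
        assert set(flagged.strategy) == {"50-GCRSS", "60-GCRSS", "65-GCRSS", "70-GCRSS"}
        assert set(flagged.dominance) <= {"dominated", "extended"}
        icers = table[table.on_frontier].icer_vs_previous.dropna().to_numpy()
        assert np.all(np.diff(icers) > 0)

    def test_simple_dominance(self):
        t = efficiency_frontier([("a", 100.0, 10.0), ("b", 50.0, 11.0)])
        assert list(t[t.on_frontier].strategy) == ["b"]
        assert t.set_index("strategy").dominance["a"] == "dominated"

    def test_needs_two_strategies(self):
        with pytest.raises(ValueError):
            efficiency_frontier([("a", 1.0, 1.0)])

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.dictionaries(st.integers(0, 50), st.integers(0, 10_000),
                           min_size=2, max_size=10))
    def test_matches_brute_force_hull(self, qaly_to_cost):
        points = [(f"s{q}", float(c), float(q)) for q, c in qaly_to_cost.items()]
        table = efficiency_frontier(points)
        assert set(table[table.on_frontier].strategy) == set(
            _brute_force_frontier(points))


class TestWtp:
    def test_published_icer_is_cost_effective(self):
        assert wtp_classify(12601) == "cost-effective"

    def test_boundaries(self):
        assert wtp_classify(0.0) == "highly cost-effective"
        assert wtp_classify(40_000.0) == "not cost-effective"
        assert wtp_classify(37_655.0) == "cost-effective"  # printed 3x threshold

    def test_gdp_must_be_positive(self):
        with pytest.raises(ValueError):
            wtp_classify(1.0, 0.0)
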