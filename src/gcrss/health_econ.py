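"""Clinical and economic endpoints: benefit/harm metrics, ICERs, the
efficiency frontier with extended dominance, and WTP classification.

Conventions (fixed for the whole package):

* counts are reported per cohort (typically per 100,000 entrants);
* life-year-based ratios use UNDISCOUNTED life-years, while costs and
  QALYs are discounted at the registry rate anchored at age 20;
* reported cells round to the nearest integer for counts (ties to even),
  one decimal for life-years gained per death averted, three decimals
  for the benefit-to-harm ratio;
* the benefit-to-harm ratio divides screening complication-related
  EVENTS (fatal or not) by GC deaths prevented; a ``harm="deaths"``
  switch substitutes complication-related deaths.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CohortResult",
    "ComparativeMetrics",
    "discount_factor",
    "comparative_metrics",
    "compute_icer",
    "efficiency_frontier",
    "wtp_classify",
    "PER_CAPITA_GDP_2021",
    "WTP_3X_GDP",
]

PER_CAPITA_GDP_2021 = 12_552.0  # USD
# three times per-capita GDP as printed in the reference setting
WTP_3X_GDP = 37_655.0


@dataclass
class CohortResult:
    """Per-strategy event tallies and per-person averages for one cohort."""

    strategy: str
    n: int
    gc_cases: int
    gc_deaths: int
    other_deaths: int
    complication_events: int
    complication_deaths: int  # fatal complications + surgery deaths
    surgery_deaths: int
    endoscopies: int
    serology_tests: int
    stage_counts: tuple  # clinical diagnoses by stage I-IV
    life_years: float    # per-person, undiscounted
    disc_cost: float     # per-person, discounted USD
    disc_qaly: float     # per-person, discounted

    def __post_init__(self):
        counts = (self.gc_cases, self.gc_deaths, self.complication_events,
                  self.complication_deaths, self.surgery_deaths,
                  self.endoscopies, self.serology_tests)
        if any(c < 0 for c in counts):
            raise ValueError("negative event count")
        if sum(self.stage_counts) != self.gc_cases:
            raise ValueError("stage counts must sum to diagnosed GC cases")
        if self.life_years <= 0:
            raise ValueError("life-years must be positive")

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "CohortResult":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        d = json.loads(text)
        d["stage_counts"] = tuple(d["stage_counts"])
        return cls(**d)


def discount_factor(age: float, rate: float) -> float:
    """Discount factor 1/(1+rate)^(age-20), anchored at model entry."""
    if age < 20:
        raise ValueError("the model starts at age 20")
    return 1.0 / (1.0 + rate) ** (age - 20)


@dataclass
class ComparativeMetrics:
    """Benefit/harm accounting of one screening strategy vs no screening.

    Unrounded values; :meth:`report` applies the reporting rounding rules.
    ``nan`` marks ratios undefined because no deaths were averted.
    """

    strategy: str
    incidence_reduction: float  # percent
    deaths_averted: int
    net_deaths_averted: int
    nns: float
    endoscopies_per_death_averted: float
    endoscopies_per_life_year_gained: float
    life_years_gained_per_death_averted: float
    life_years_gained: float
    benefit_to_harm_ratio: float

    def report(self) -> dict:
        r = lambda x: float("nan") if math.isnan(x) else int(np.round(x))
        return {
            "strategy": self.strategy,
            "incidence_reduction_pct": float(np.round(self.incidence_reduction, 1)),
            "deaths_averted": self.deaths_averted,
            "net_deaths_averted": self.net_deaths_averted,
            "nns": r(self.nns),
            "endoscopies_per_death_averted": r(self.endoscopies_per_death_averted),
            "endoscopies_per_life_year_gained": r(self.endoscopies_per_life_year_gained),
            "life_years_gained_per_death_averted":
                float(np.round(self.life_years_gained_per_death_averted, 1)),
            "benefit_to_harm_ratio": float(np.round(self.benefit_to_harm_ratio, 3)),
        }


def comparative_metrics(result: CohortResult, reference: CohortResult,
                        harm: str = "events") -> ComparativeMetrics:
    """Derive the strategy-vs-no-screening metrics from two cohorts.

    ``reference`` must be a no-screening cohort of the same size (ideally
    simulated with common random numbers).  Life-years gained are computed
    on undiscounted per-person values scaled by n.
    """
    if result.n != reference.n:
        raise ValueError("cohorts must have equal n")
    if harm not in ("events", "deaths"):
        raise ValueError("harm must be 'events' or 'deaths'")
    n = result.n
    deaths_averted = reference.gc_deaths - result.gc_deaths
    net = deaths_averted - result.complication_deaths
    ly_gained = (result.life_years - reference.life_years) * n
    harm_count = (result.complication_events if harm == "events"
                  else result.complication_deaths)
    if deaths_averted > 0:
        nns = n / deaths_averted
        epda = result.endoscopies / deaths_averted
        lypda = ly_gained / deaths_averted
        bth = harm_count / deaths_averted
    else:
        nns = epda = lypda = bth = float("nan")
    eplyg = result.endoscopies / ly_gained if ly_gained > 0 else float("nan")
    inc_red = (1.0 - result.gc_cases / reference.gc_cases) * 100.0 \
        if reference.gc_cases > 0 else float("nan")
    return ComparativeMetrics(
        strategy=result.strategy,
        incidence_reduction=inc_red,
        deaths_averted=deaths_averted,
        net_deaths_averted=net,
        nns=nns,
        endoscopies_per_death_averted=epda,
        endoscopies_per_life_year_gained=eplyg,
        life_years_gained_per_death_averted=lypda,
        life_years_gained=ly_gained,
        benefit_to_harm_ratio=bth,
    )


def compute_icer(cost_a: float, qaly_a: float, cost_b: float, qaly_b: float):
    """Incremental cost per QALY of a vs b, or a dominance verdict.

    Returns the ratio when the QALYs differ; "dominated" when a costs at
    least as much for no more QALYs (strictly worse somewhere), "dominant"
    for the mirror case.  Identical pairs are flagged as an error.
    """
    dc, dq = cost_a - cost_b, qaly_a - qaly_b
    if dc == 0 and dq == 0:
        raise ValueError("identical cost and QALY pairs: ICER undefined")
    if dq == 0:
        return "dominated" if dc > 0 else "dominant"
    if dq < 0:
        return "dominated" if dc >= 0 else dc / dq
    if dc <= 0:
        return "dominant"
    return dc / dq


def wtp_classify(icer: float, per_capita_gdp: float = PER_CAPITA_GDP_2021) -> str:
    """WHO-style value classification against 1x and 3x per-capita GDP."""
    if per_capita_gdp <= 0:
        raise ValueError("per-capita GDP must be positive")
    three_x = WTP_3X_GDP if per_capita_gdp == PER_CAPITA_GDP_2021 else 3.0 * per_capita_gdp
    if icer < per_capita_gdp:
        return "highly cost-effective"
    if icer <= three_x:
        return "cost-effective"
    return "not cost-effective"


def efficiency_frontier(cea_inputs, per_capita_gdp: float = PER_CAPITA_GDP_2021
                        ) -> pd.DataFrame:
    """Cross-strategy incremental analysis.

    ``cea_inputs``: iterable of (strategy, cost, qaly).  Strictly dominated
    strategies are removed first, then extended dominance prunes any
    strategy whose incremental ICER exceeds that of a later, more effective
    option; the surviving frontier has strictly increasing costs, QALYs and
    incremental ICERs.  Returns a CEA table with dominance flags, frontier
    membership, ICERs vs the least-costly strategy and vs the previous
    frontier member, and the WTP class of the frontier ICER.
    """
    items = [(str(s), float(c), float(q)) for s, c, q in cea_inputs]
    if len(items) < 2:
        raise ValueError("need at least two strategies")
    order = sorted(range(len(items)), key=lambda i: (items[i][2], items[i][1]))
    dominance = {i: "none" for i in range(len(items))}

    # strict dominance: someone is no worse on both axes, better on one
    for i, (_, ci, qi) in enumerate(items):
        for j, (_, cj, qj) in enumerate(items):
            if i != j and cj <= ci and qj >= qi and (cj < ci or qj > qi):
                dominance[i] = "dominated"
                break

    frontier = [i for i in order if dominance[i] == "none"]
    # extended dominance: prune while incremental ICERs are not increasing
    changed = True
    while changed and len(frontier) > 2:
        changed = False
        icers = [
            (items[frontier[k]][1] - items[frontier[k - 1]][1])
            / (items[frontier[k]][2] - items[frontier[k - 1]][2])
            for k in range(1, len(frontier))
        ]
        for k in range(len(icers) - 1):
            if icers[k] >= icers[k + 1]:
                dominance[frontier[k + 1]] = "extended"
                frontier.pop(k + 1)
                changed = True
                break

    ref = min(range(len(items)), key=lambda i: items[i][1])
    rows = []
    prev = None
    for i in order:
        s, c, q = items[i]
        on_front = dominance[i] == "none"
        icer_ref = None
        if i != ref:
            v = compute_icer(c, q, items[ref][1], items[ref][2])
            icer_ref = v if isinstance(v, float) else None
        icer_prev = None
        if on_front and prev is not None:
            icer_prev = (c - items[prev][1]) / (q - items[prev][2])
        rows.append({
            "strategy": s, "cost": c, "qaly": q,
            "icer_vs_reference": icer_ref,
            "icer_vs_previous": icer_prev,
            "dominance": dominance[i],
            "on_frontier": on_front,
            "wtp_class": wtp_classify(icer_ref, per_capita_gdp)
            if icer_ref is not None else None,
        })
        if on_front:
            prev = i
    return pd.DataFrame(rows)
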