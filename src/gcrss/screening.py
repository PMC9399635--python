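"""Risk-stratified serology + endoscopy screening (GCRSS protocol).

Serum Hp antibody together with pepsinogen / gastrin-17 "atrophy status"
stratifies screenees into four risk levels:

    A: Hp(-) atrophy(-)  -> serology retest every 5 years
    B: Hp(+) atrophy(-)  -> endoscopy every 3 years + Hp eradication
    C: Hp(+) atrophy(+)  -> endoscopy every 2 years + Hp eradication
    D: Hp(-) atrophy(+)  -> endoscopy every 1 year

Endoscopy-detected dysplasia or asymptomatic stage-I cancer is resected
(ESD or surgery, with bleeding/perforation complications and a surgery
death risk); screen-detected stage II-IV becomes clinical cancer at once.
Levels B/C/D are sticky: only level A is serologically retested and can
be promoted.  Adherence is perfect.

Two surfaces: a scalar per-individual API mirroring the engine, and the
vectorized :func:`screening_step` the cohort engine calls each cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

from . import _rng
from ._rng import CounterRng, uniform
from .model_params import (
    ATROPHY_STATES,
    HealthState,
    ParameterSet,
)

if TYPE_CHECKING:  # pragma: no cover
    from .natural_history import Individual

__all__ = [
    "SerologyResult",
    "ScreeningPolicy",
    "EndoscopyOutcome",
    "classify_risk_level",
    "perform_serology",
    "perform_endoscopy",
    "eradicate_hp",
    "run_policy_for_year",
]

START_AGES = (40, 45, 50, 55, 60, 65, 70)
LEVEL_INTERVALS = {"A": 5, "B": 3, "C": 2, "D": 1}
# integer codes used by the vectorized engine
LEVEL_CODE = {"unassigned": 0, "A": 1, "B": 2, "C": 3, "D": 4}
CODE_LEVEL = {v: k for k, v in LEVEL_CODE.items()}
_INTERVAL_BY_CODE = np.array([0, 5, 3, 2, 1])


@dataclass(frozen=True)
class SerologyResult:
    """Observed (not necessarily true) Hp and atrophy status."""

    hp_positive: bool
    atrophy_positive: bool


@dataclass(frozen=True)
class ScreeningPolicy:
    """A GCRSS strategy: first screen at ``start_age``, then level rules."""

    start_age: int
    level_intervals: dict = field(default_factory=lambda: dict(LEVEL_INTERVALS))

    def __post_init__(self):
        if self.start_age not in START_AGES:
            raise ValueError(f"start age must be one of {START_AGES}")
        if any(int(v) < 1 for v in self.level_intervals.values()):
            raise ValueError("screening intervals must be positive integers")

    @property
    def label(self) -> str:
        return f"{self.start_age}-GCRSS"

    @classmethod
    def parse(cls, strategy):
        """'none'/None -> None; 40 or '40-GCRSS' -> policy."""
        if strategy is None or (isinstance(strategy, str)
                                and strategy.lower().replace(" ", "_")
                                in ("none", "no_screening")):
            return None
        if isinstance(strategy, ScreeningPolicy):
            return strategy
        if isinstance(strategy, str) and strategy.endswith("-GCRSS"):
            return cls(int(strategy.split("-")[0]))
        return cls(int(strategy))


@dataclass
class EndoscopyOutcome:
    finding: str  # "negative" | "dysplasia" | "GC stage I".."GC stage IV"
    complication: str = "none"  # "none" | "bleeding" | "perforation"
    death: bool = False
    treatment_given: str = "none"  # "none" | "esd" | "surgery"


def classify_risk_level(serology: SerologyResult) -> str:
    """Exact truth-table mapping of the serology pattern to levels A-D."""
    if serology.hp_positive:
        return "C" if serology.atrophy_positive else "B"
    return "D" if serology.atrophy_positive else "A"


def _true_atrophy(state: HealthState) -> bool:
    return HealthState(state) in ATROPHY_STATES


def _require_alive(individual) -> None:
    if individual.state in (HealthState.DeathGC, HealthState.DeathOther):
        raise ValueError("operation not permitted on a dead individual")


# ---------------------------------------------------------------------------
# scalar per-individual operations
# ---------------------------------------------------------------------------

def perform_serology(individual: "Individual", ps: ParameterSet, rng: CounterRng) -> SerologyResult:
    """Draw observed Hp/atrophy status through the assay error model and
    accrue the (discounted) serology cost."""
    _require_alive(individual)
    age = individual.age
    u_hp = rng.u(age, _rng.SEROLOGY_HP)
    u_at = rng.u(age, _rng.SEROLOGY_ATROPHY)
    if individual.profile.hp_infected:
        hp_obs = u_hp < ps.value("sens_hp_serology")
    else:
        hp_obs = u_hp < 1.0 - ps.value("spec_hp_serology")
    if _true_atrophy(individual.state):
        at_obs = u_at < ps.value("sens_atrophy_serology")
    else:
        at_obs = u_at < 1.0 - ps.value("spec_atrophy_serology")
    individual.add_cost("serology", ps.value("cost_serology"), ps.value("discount_rate"))
    individual.tallies["serology_tests"] += 1
    return SerologyResult(bool(hp_obs), bool(at_obs))


def eradicate_hp(individual: "Individual", ps: ParameterSet, rng: CounterRng) -> "Individual":
    """Quadruple-therapy Hp eradication for levels B/C: therapy cost always
    accrues; infection clears with the eradication-success probability and
    never reverts.  A false-positive serology buys the cost with no effect."""
    if individual.screening_level not in ("B", "C"):
        raise ValueError("eradication therapy is offered to levels B and C only")
    individual.add_cost("hp_therapy", ps.value("cost_hp_therapy"), ps.value("discount_rate"))
    if individual.profile.hp_infected:
        if rng.u(individual.age, _rng.ERADICATION) < ps.value("hp_eradication_success"):
            individual.profile.hp_infected = False
            individual.treated_flags["hp_eradicated"] = True
    return individual


def perform_endoscopy(individual: "Individual", ps: ParameterSet, rng: CounterRng) -> EndoscopyOutcome:
    """One endoscopy: imperfect, grade-specific lesion detection, then
    resection (dysplasia / preclinical stage I) or immediate clinical
    conversion (preclinical stage II-IV), with complications."""
    _require_alive(individual)
    age = individual.age
    r = ps.value("discount_rate")
    individual.add_cost("endoscopy", ps.value("cost_endoscopy"), r)
    individual.tallies["endoscopies"] += 1
    u = rng.u(age, _rng.ENDO_DETECT)
    st = HealthState(individual.state)

    outcome = EndoscopyOutcome("negative")
    if st == HealthState.Dysplasia and u < ps.value("sens_endo_dysplasia"):
        outcome.finding = "dysplasia"
        if not (individual.treated_flags["post_esd"] or individual.treated_flags["post_surgery"]):
            _treat_lesion(individual, ps, rng, outcome, ps.value("esd_fraction_dysplasia"))
    elif st == HealthState.PreclinicalGC_I and u < ps.value("sens_endo_pre1"):
        outcome.finding = "GC stage I"
        _treat_lesion(individual, ps, rng, outcome, ps.value("esd_fraction_stage1"))
        if not outcome.death:
            individual.state = HealthState.ClinicalGC_I
            individual.years_in_state = 0
    elif st in (HealthState.PreclinicalGC_II, HealthState.PreclinicalGC_III,
                HealthState.PreclinicalGC_IV):
        k = int(st) - int(HealthState.PreclinicalGC_I) + 1
        if u < ps.value(f"sens_endo_pre{k}"):
            outcome.finding = f"GC stage {'I' * min(k, 3) if k < 4 else 'IV'}"
            outcome.finding = ("GC stage I", "GC stage II", "GC stage III", "GC stage IV")[k - 1]
            individual.state = HealthState(int(HealthState.ClinicalGC_I) + k - 1)
            individual.years_in_state = 0
    elif st in (HealthState.Normal, HealthState.NonAtrophicGastritis,
                HealthState.AtrophicGastritis, HealthState.IntestinalMetaplasia):
        if u < 1.0 - ps.value("spec_endoscopy"):
            # false positive: confirmatory biopsy cost, no treatment
            individual.add_cost("biopsy", ps.value("cost_biopsy"), r)
    return outcome


def _treat_lesion(individual, ps, rng, outcome, esd_fraction):
    """ESD-or-surgery choice with complications; mutates individual/outcome."""
    age = individual.age
    r = ps.value("discount_rate")
    esd = rng.u(age, _rng.TREAT_CHOICE) < esd_fraction
    outcome.treatment_given = "esd" if esd else "surgery"
    if esd:
        individual.add_cost("esd", ps.value("cost_esd"), r)
        individual.treated_flags["post_esd"] = True
        pb, pp = ps.value("p_bleeding_esd"), ps.value("p_perforation_esd")
    else:
        individual.add_cost("surgery", ps.value("cost_surgery"), r)
        individual.treated_flags["post_surgery"] = True
        pb, pp = ps.value("p_bleeding_surgery"), ps.value("p_perforation_surgery")
    pf = ps.value("p_complication_fatal")
    if rng.u(age, _rng.BLEEDING) < pb:
        outcome.complication = "bleeding"
        individual.tallies["complications_bleeding"] += 1
        individual.add_cost("complication", ps.value("cost_bleeding"), r)
        if rng.u(age, _rng.BLEEDING_FATAL) < pf:
            outcome.death = True
            individual.die("complication")
    if not outcome.death and rng.u(age, _rng.PERFORATION) < pp:
        outcome.complication = "perforation"
        individual.tallies["complications_perforation"] += 1
        individual.add_cost("complication", ps.value("cost_perforation"), r)
        if rng.u(age, _rng.PERFORATION_FATAL) < pf:
            outcome.death = True
            individual.die("complication")
    if not outcome.death and not esd:
        if rng.u(age, _rng.SURGERY_DEATH) < ps.value("p_surgery_death"):
            outcome.death = True
            individual.die("surgery")


def run_policy_for_year(individual: "Individual", policy: ScreeningPolicy,
                        ps: ParameterSet, rng: CounterRng) -> "Individual":
    """Execute whatever screening the policy schedules at the current age."""
    _require_alive(individual)
    if policy is None or individual.age < policy.start_age:
        return individual
    if individual.state in (HealthState.ClinicalGC_I, HealthState.ClinicalGC_II,
                            HealthState.ClinicalGC_III, HealthState.ClinicalGC_IV):
        return individual  # symptomatic patients have left the program
    if individual.age < individual.next_screen_due and individual.screening_level != "unassigned":
        return individual
    if individual.screening_level in ("unassigned", "A"):
        serology = perform_serology(individual, ps, rng)
        level = classify_risk_level(serology)
        individual.screening_level = level
        individual.next_screen_due = individual.age + policy.level_intervals[level]
        if level in ("B", "C"):
            eradicate_hp(individual, ps, rng)
    else:
        level = individual.screening_level
        individual.next_screen_due = individual.age + policy.level_intervals[level]
        perform_endoscopy(individual, ps, rng)
    return individual


# ---------------------------------------------------------------------------
# vectorized screening step (called by the cohort engine once per cycle)
# ---------------------------------------------------------------------------

def screening_step(coh, age: int, policy: ScreeningPolicy, arr, seed: int, log=None):
    """Apply one year of the policy to the cohort arrays in place.

    Mirrors the scalar API above draw-for-draw (same purpose codes), so a
    one-person cohort reproduces the scalar path.
    """
    pv = arr.pv
    df = arr.df[age - 20]
    S = coh.state
    active = coh.alive() & coh.in_program & (age >= policy.start_age)
    if not active.any():
        return
    due = active & ((coh.next_screen <= age) | (coh.level == 0))
    # symptomatic cancer has left the program (engine also clears the flag)
    due &= ~np.isin(S, (9, 10, 11, 12))
    if not due.any():
        return

    # --- serology: unassigned or level A ---
    ser = due & (coh.level <= 1)
    if ser.any():
        idx = np.where(ser)[0]
        ids = coh.ids[idx]
        coh.n_serology[idx] += 1
        coh.disc_cost[idx] += pv["cost_serology"] * df
        u_hp = uniform(seed, ids, age, _rng.SEROLOGY_HP)
        u_at = uniform(seed, ids, age, _rng.SEROLOGY_ATROPHY)
        hp_true = coh.hp[idx]
        at_true = (S[idx] >= 2) & (S[idx] <= 8)
        obs_hp = np.where(hp_true, u_hp < pv["sens_hp_serology"],
                          u_hp < 1.0 - pv["spec_hp_serology"])
        obs_at = np.where(at_true, u_at < pv["sens_atrophy_serology"],
                          u_at < 1.0 - pv["spec_atrophy_serology"])
        new_level = np.where(obs_hp, np.where(obs_at, 3, 2), np.where(obs_at, 4, 1))
        coh.level[idx] = new_level
        coh.next_screen[idx] = age + _INTERVAL_BY_CODE[new_level]
        # eradication therapy for everyone stratified into B/C (observed Hp+)
        bc = idx[(new_level == 2) | (new_level == 3)]
        if bc.size:
            coh.disc_cost[bc] += pv["cost_hp_therapy"] * df
            u_er = uniform(seed, coh.ids[bc], age, _rng.ERADICATION)
            cured = coh.hp[bc] & (u_er < pv["hp_eradication_success"])
            coh.hp[bc[cured]] = False
            coh.hp_eradicated[bc[cured]] = True
        if log is not None and log.enabled:
            for i, lv in zip(idx, new_level):
                log.append(int(coh.ids[i]), age, f"serology->level {CODE_LEVEL[int(lv)]}",
                           int(S[i]), int(S[i]), pv["cost_serology"] * df, None)

    # --- endoscopy: levels B, C, D ---
    endo = due & (coh.level >= 2)
    if not endo.any():
        return
    idx = np.where(endo)[0]
    ids = coh.ids[idx]
    coh.n_endoscopy[idx] += 1
    coh.disc_cost[idx] += pv["cost_endoscopy"] * df
    coh.next_screen[idx] = age + _INTERVAL_BY_CODE[coh.level[idx]]
    u = uniform(seed, ids, age, _rng.ENDO_DETECT)
    st = S[idx]
    if log is not None and log.enabled:
        for i in idx:
            log.append(int(coh.ids[i]), age, "endoscopy", int(S[i]), int(S[i]),
                       pv["cost_endoscopy"] * df, None)

    # false positives on lesion-free mucosa: biopsy cost only
    fp = (st <= 3) & (u < 1.0 - pv["spec_endoscopy"])
    coh.disc_cost[idx[fp]] += pv["cost_biopsy"] * df

    det_dys = (st == 4) & (u < pv["sens_endo_dysplasia"])
    treat_dys = det_dys & (coh.treat[idx] == 0)  # treated dysplasia is surveilled, not re-resected
    det_pre = np.zeros_like(det_dys)
    for k in range(1, 5):
        det_pre |= (st == 4 + k) & (u < pv[f"sens_endo_pre{k}"])
    conv = idx[det_pre]
    if conv.size:  # screen-detected cancer becomes (treated) clinical cancer
        stage = S[conv] - 4  # 1..4
        new_state = 8 + stage
        for k in range(1, 5):
            coh.stage_counts[k - 1] += int(np.sum(stage == k))
        coh.gc_cases += conv.size
        S[conv] = new_state
        coh.years_in_state[conv] = 0
        coh.in_program[conv] = False
        if log is not None and log.enabled:
            for i, ns in zip(conv, new_state):
                log.append(int(coh.ids[i]), age, "screen-detected GC",
                           int(4 + (ns - 8)), int(ns), 0.0, None)

    # --- resection for detected dysplasia and screen-detected stage I ---
    resect = np.concatenate([idx[treat_dys], conv[S[conv] == 9]])
    if resect.size == 0:
        return
    u_choice = uniform(seed, coh.ids[resect], age, _rng.TREAT_CHOICE)
    frac = np.where(S[resect] == 4, pv["esd_fraction_dysplasia"], pv["esd_fraction_stage1"])
    is_esd = u_choice < frac
    esd_i, surg_i = resect[is_esd], resect[~is_esd]
    coh.disc_cost[esd_i] += pv["cost_esd"] * df
    coh.disc_cost[surg_i] += pv["cost_surgery"] * df
    coh.treat[esd_i] = np.maximum(coh.treat[esd_i], 1)
    coh.treat[surg_i] = 2

    dead = np.zeros(resect.size, dtype=bool)
    pf = pv["p_complication_fatal"]
    p_bleed = np.where(is_esd, pv["p_bleeding_esd"], pv["p_bleeding_surgery"])
    p_perf = np.where(is_esd, pv["p_perforation_esd"], pv["p_perforation_surgery"])
    u_b = uniform(seed, coh.ids[resect], age, _rng.BLEEDING)
    bleed = u_b < p_bleed
    coh.complication_events += int(bleed.sum())
    coh.disc_cost[resect[bleed]] += pv["cost_bleeding"] * df
    u_bf = uniform(seed, coh.ids[resect], age, _rng.BLEEDING_FATAL)
    fatal_b = bleed & (u_bf < pf)
    dead |= fatal_b
    u_p = uniform(seed, coh.ids[resect], age, _rng.PERFORATION)
    perf = ~dead & (u_p < p_perf)
    coh.complication_events += int(perf.sum())
    coh.disc_cost[resect[perf]] += pv["cost_perforation"] * df
    u_pf = uniform(seed, coh.ids[resect], age, _rng.PERFORATION_FATAL)
    fatal_p = perf & (u_pf < pf)
    dead |= fatal_p
    if fatal_b.any() or fatal_p.any():
        comp_dead = resect[fatal_b | fatal_p]
        coh.cause[comp_dead] = 4
        coh.complication_deaths += comp_dead.size
    u_s = uniform(seed, coh.ids[resect], age, _rng.SURGERY_DEATH)
    surg_dead = ~dead & ~is_esd & (u_s < pv["p_surgery_death"])
    if surg_dead.any():
        sd = resect[surg_dead]
        coh.cause[sd] = 3
        coh.surgery_deaths += sd.size
        dead |= surg_dead
    if dead.any():
        di = resect[dead]
        S[di] = 14  # non-GC death; cause codes distinguish surgery/complication
        coh.in_program[di] = False
        coh.died_in_screening[di] = True
    if log is not None and log.enabled:
        for j, i in enumerate(resect):
            log.append(int(coh.ids[i]), age,
                       "esd" if is_esd[j] else "surgery", int(S[i]), int(S[i]),
                       0.0, None)
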