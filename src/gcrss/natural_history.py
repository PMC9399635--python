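"""Discrete-time (1-year cycle) individual-level natural-history engine.

Each simulated person enters at age 20 with a risk profile (sex, Hp
infection, smoking) and moves annually through the precancerous cascade,
preclinical and clinical cancer, under competing background and
stage-specific cancer mortality, until death or age 100.  Within a cycle
the order is: screening (if due) -> transition sampling -> accrual.

Competing risks are combined as background death first, then GC death
among survivors (clinical states only), then progression among the
remainder, so each row of the transition kernel sums to one exactly.
Risk-ratio multipliers act on the probability scale and are capped at 1.

All stochastic draws come from counter-based substreams keyed by
(seed, individual id), so cohorts are reproducible bit-for-bit, results
do not depend on processing order, and the same individual re-uses the
same stream under every strategy (common random numbers).

A deterministic cohort-matrix oracle (forward multiplication of expected
state occupancy over risk-profile strata) provides exact expectations
for the no-screening case; it shares the transition-kernel builder with
the microsimulation, so the two can disagree only by Monte-Carlo noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _rng
from ._rng import CounterRng, uniform
from .health_econ import CohortResult
from .model_params import (
    ENTRY_AGE,
    MAX_AGE,
    HealthState,
    LifeTable,
    ParameterSet,
    RiskProfile,
    _AGE_MULT,
    age_band_index,
)
from .screening import ScreeningPolicy, screening_step

logger = logging.getLogger("gcrss")

__all__ = [
    "Individual",
    "EventLog",
    "EngineArrays",
    "build_arrays",
    "annual_transition_probabilities",
    "advance_cycle",
    "simulate_cohort",
    "cohort_matrix_oracle",
    "OracleResult",
]

_AGES = np.arange(ENTRY_AGE, MAX_AGE + 1)
N_AGES = len(_AGES)
N_STATES = 15
_SMOKE_CODE = {"never": 0, "light": 1, "heavy": 2}
_CAUSES = ("none", "gc", "other", "surgery", "complication")


def stratum_index(sex, hp, smoke, treat):
    """Flat index into the (2 sex x 2 Hp x 3 smoking x 3 treatment) strata."""
    return ((np.asarray(sex) * 2 + np.asarray(hp)) * 3 + np.asarray(smoke)) * 3 + np.asarray(treat)


N_STRATA = 36


class EngineArrays:
    """Transition kernels for every (age, stratum) plus accrual vectors."""

    def __init__(self, M, df, state_cost, state_util, pv):
        self.M = M            # (N_AGES, N_STRATA, 15, 15)
        self.df = df          # discount factor by age index
        self.state_cost = state_cost
        self.state_util = state_util
        self.pv = pv          # plain dict of parameter base values


def build_arrays(ps: ParameterSet, lt: LifeTable) -> EngineArrays:
    pv = ps.values()
    M = np.zeros((N_AGES, N_STRATA, N_STATES, N_STATES))
    band = age_band_index(_AGES)
    onset = np.minimum(pv["p_normal_nag"] * _AGE_MULT[band], 1.0)  # (N_AGES,)

    adv = np.array([pv[f"p_advance_{k}"] for k in (1, 2, 3)]) * pv["advance_scale"]
    srf = np.array([pv[f"p_surface_{k}"] for k in (1, 2, 3, 4)]) * pv["surface_scale"]
    gc_mort = np.array([pv[f"gc_mortality_{k}"] for k in (1, 2, 3, 4)])
    treat_rr = {0: 1.0, 1: pv["rr_progression_after_esd"], 2: pv["rr_progression_after_surgery"]}
    smoke_rr = {0: 1.0, 1: pv["rr_smoking_light"], 2: pv["rr_smoking_heavy"]}
    capped = False

    for sex in (0, 1):
        qbg = lt.qx(_AGES, sex)
        qbg = qbg.copy()
        qbg[-1] = 1.0  # the model ends at age 100
        for hp in (0, 1):
            p12 = pv["p_nag_ag"] * (pv["rr_hp_atrophy"] if hp else 1.0)
            if p12 > 1.0:
                capped = True
            p12 = min(p12, 1.0)
            for smoke in (0, 1, 2):
                p34 = min(pv["p_im_dys"] * smoke_rr[smoke], 1.0)
                for treat in (0, 1, 2):
                    s = stratum_index(sex, hp, smoke, treat)
                    p45 = min(pv["p_dys_pre1"] * treat_rr[treat], 1.0)
                    K = np.zeros((N_AGES, N_STATES, N_STATES))
                    surv = 1.0 - qbg

                    def alive_row(state, out_probs):
                        """out_probs: list of (to_state, p array-or-scalar)."""
                        total = np.zeros(N_AGES)
                        for to, p in out_probs:
                            p = np.broadcast_to(np.minimum(p, 1.0), (N_AGES,))
                            K[:, state, to] = surv * p
                            total = total + p
                        over = total > 1.0
                        if over.any():  # proportional cap, residual stay = 0
                            scale = np.where(over, 1.0 / np.maximum(total, 1e-300), 1.0)
                            for to, p in out_probs:
                                p = np.broadcast_to(np.minimum(p, 1.0), (N_AGES,))
                                K[:, state, to] = surv * p * scale
                            total = np.minimum(total, 1.0)
                        K[:, state, 14] += qbg
                        K[:, state, state] += surv * (1.0 - total)

                    alive_row(0, [(1, onset)])
                    alive_row(1, [(2, p12)])
                    alive_row(2, [(3, pv["p_ag_im"])])
                    alive_row(3, [(4, p34)])
                    alive_row(4, [(5, p45)])
                    # preclinical: stage advance competes with surfacing
                    for k in range(4):
                        outs = [(9 + k, srf[k])]
                        if k < 3:
                            outs.insert(0, (6 + k, adv[k]))
                        alive_row(5 + k, outs)
                    # clinical: GC death after background death; stage-I
                    # mortality is reduced by resection ("residual lesion")
                    for k in range(4):
                        m = gc_mort[k] * (treat_rr[treat] if k == 0 else 1.0)
                        K[:, 9 + k, 14] = qbg
                        K[:, 9 + k, 13] = surv * m
                        K[:, 9 + k, 9 + k] = surv * (1.0 - m)
                    K[:, 13, 13] = 1.0
                    K[:, 14, 14] = 1.0
                    M[:, s] = K
    if capped:
        logger.warning("transition probabilities exceeded 1 after RR application; capped")
    r = pv["discount_rate"]
    df = (1.0 + r) ** -(_AGES - ENTRY_AGE).astype(float)
    state_cost = np.zeros(N_STATES)
    state_util = np.zeros(N_STATES)
    state_util[:13] = pv["utility_noncancer"]
    for k in range(4):
        state_cost[9 + k] = pv[f"cost_gc_stage{k + 1}"]
        state_util[9 + k] = pv[f"utility_stage{k + 1}"]
    return EngineArrays(M, df, state_cost, state_util, pv)


# ---------------------------------------------------------------------------
# scalar per-individual surface
# ---------------------------------------------------------------------------

@dataclass
class Individual:
    """One simulated person: true state, risk profile, screening bookkeeping
    and accrued outcomes."""

    id: int
    age: int
    profile: RiskProfile
    state: HealthState = HealthState.Normal
    years_in_state: int = 0
    screening_level: str = "unassigned"
    next_screen_due: int = 0
    treated_flags: dict = field(default_factory=lambda: {
        "post_esd": False, "post_surgery": False, "hp_eradicated": False})
    tallies: dict = field(default_factory=lambda: {
        "endoscopies": 0, "serology_tests": 0,
        "complications_bleeding": 0, "complications_perforation": 0,
        "cost": {}, "disc_cost": 0.0, "disc_qaly": 0.0, "life_years": 0.0})
    cause_of_death: str = "none"

    @property
    def alive(self) -> bool:
        return self.state not in (HealthState.DeathGC, HealthState.DeathOther)

    def add_cost(self, category: str, amount: float, rate: float) -> None:
        if not self.alive:
            raise ValueError("dead individuals accrue nothing")
        d = amount / (1.0 + rate) ** (self.age - ENTRY_AGE)
        self.tallies["cost"][category] = self.tallies["cost"].get(category, 0.0) + amount
        self.tallies["disc_cost"] += d

    def die(self, cause: str) -> None:
        if cause not in _CAUSES:
            raise ValueError(f"unknown cause {cause!r}")
        self.state = HealthState.DeathGC if cause == "gc" else HealthState.DeathOther
        self.cause_of_death = cause
        self.years_in_state = 0


class EventLog:
    """Append-only per-cycle event records (id, age, event, states, cost)."""

    def __init__(self, enabled: bool = True):
        self.enabled = enabled
        self._rows: list = []

    def append(self, id, age, event, state_before, state_after, cost, utility):
        self._rows.append((id, age, event, state_before, state_after, cost, utility))

    def __len__(self):
        return len(self._rows)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self._rows, columns=[
            "id", "age", "event", "state_before", "state_after", "cost", "utility"])

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _stratum_of(individual: Individual) -> int:
    p = individual.profile
    treat = 2 if individual.treated_flags["post_surgery"] else (
        1 if individual.treated_flags["post_esd"] else 0)
    return int(stratum_index(0 if p.sex == "male" else 1,
                             int(p.hp_infected), _SMOKE_CODE[p.smoking], treat))


def annual_transition_probabilities(individual: Individual, ps: ParameterSet,
                                    lt: LifeTable) -> dict:
    """Full to-state probability map for the coming cycle (sums to 1)."""
    if not individual.alive:
        raise ValueError("no transitions for a dead individual")
    arr = build_arrays(ps, lt)
    ai = min(individual.age, MAX_AGE) - ENTRY_AGE
    row = arr.M[ai, _stratum_of(individual), int(individual.state)]
    return {HealthState(j): float(row[j]) for j in range(N_STATES)}


def advance_cycle(individual: Individual, ps: ParameterSet, lt: LifeTable,
                  rng: CounterRng) -> Individual:
    """Sample one annual transition and accrue life-years, QALYs and costs
    (half-cycle credit in the year of death; discounting anchored at 20)."""
    if rng is None:
        raise ValueError("a CounterRng is required for reproducibility")
    if not individual.alive:
        raise ValueError("cannot advance a dead individual")
    probs = annual_transition_probabilities(individual, ps, lt)
    u = rng.u(individual.age, _rng.TRANSITION)
    cum = 0.0
    new_state = individual.state
    for state_j, p in probs.items():
        cum += p
        if u < cum:
            new_state = state_j
            break
    died = new_state in (HealthState.DeathGC, HealthState.DeathOther)
    w = 0.5 if died else 1.0
    pv = ps.values()
    dfac = (1.0 + pv["discount_rate"]) ** -(individual.age - ENTRY_AGE)
    util = (pv[f"utility_stage{int(individual.state) - 8}"]
            if HealthState.ClinicalGC_I <= individual.state <= HealthState.ClinicalGC_IV
            else pv["utility_noncancer"])
    individual.tallies["life_years"] += w
    individual.tallies["disc_qaly"] += w * util * dfac
    if HealthState.ClinicalGC_I <= individual.state <= HealthState.ClinicalGC_IV:
        individual.add_cost(f"gc_stage{int(individual.state) - 8}",
                            pv[f"cost_gc_stage{int(individual.state) - 8}"],
                            pv["discount_rate"])
    if new_state != individual.state:
        individual.years_in_state = 0
        if died:
            individual.cause_of_death = "gc" if new_state == HealthState.DeathGC else "other"
    else:
        individual.years_in_state += 1
    individual.state = HealthState(new_state)
    individual.age += 1
    return individual


# ---------------------------------------------------------------------------
# vectorized cohort
# ---------------------------------------------------------------------------

class _Cohort:
    """Plain array-of-fields container the engine and screening step share."""

    def __init__(self, n, seed, pv, profile_override=None, id_offset=0):
        ids = np.arange(id_offset, id_offset + n, dtype=np.uint64)
        self.ids = ids
        self.sex = (uniform(seed, ids, 0, _rng.INIT_SEX) >= pv["male_fraction"]).astype(np.int8)
        self.hp = uniform(seed, ids, 0, _rng.INIT_HP) < pv["hp_prevalence"]
        smoke_prev = np.where(self.sex == 0, pv["smoking_prev_male"], pv["smoking_prev_female"])
        smoker = uniform(seed, ids, 0, _rng.INIT_SMOKING) < smoke_prev
        heavy = uniform(seed, ids, 0, _rng.INIT_SMOKING_HEAVY) < pv["heavy_smoker_fraction"]
        self.smoke = np.where(smoker, np.where(heavy, 2, 1), 0).astype(np.int8)
        if profile_override:
            if "hp" in profile_override:
                self.hp = np.full(n, bool(profile_override["hp"]))
            if "smoking" in profile_override:
                lv = profile_override["smoking"]
                if lv == "current":  # light/heavy split preserved
                    self.smoke = np.where(heavy, 2, 1).astype(np.int8)
                else:
                    self.smoke = np.full(n, _SMOKE_CODE[lv], dtype=np.int8)
            if "sex" in profile_override:
                self.sex = np.full(n, 0 if profile_override["sex"] == "male" else 1,
                                   dtype=np.int8)
        self.state = np.zeros(n, dtype=np.int16)
        self.years_in_state = np.zeros(n, dtype=np.int16)
        self.treat = np.zeros(n, dtype=np.int8)  # 0 none, 1 post-ESD, 2 post-surgery
        self.level = np.zeros(n, dtype=np.int8)
        self.next_screen = np.zeros(n, dtype=np.int16)
        self.in_program = np.ones(n, dtype=bool)
        self.cause = np.zeros(n, dtype=np.int8)  # index into _CAUSES
        self.hp_eradicated = np.zeros(n, dtype=bool)
        self.died_in_screening = np.zeros(n, dtype=bool)
        self.disc_cost = np.zeros(n)
        self.disc_qaly = np.zeros(n)
        self.life_years = np.zeros(n)
        self.n_endoscopy = np.zeros(n, dtype=np.int32)
        self.n_serology = np.zeros(n, dtype=np.int32)
        # cohort-level tallies
        self.gc_cases = 0
        self.stage_counts = np.zeros(4, dtype=np.int64)
        self.complication_events = 0
        self.complication_deaths = 0
        self.surgery_deaths = 0

    def alive(self):
        return self.state < 13


def simulate_cohort(n, strategy, parameter_set: ParameterSet, life_table: LifeTable,
                    seed: int, *, profile_override=None, log_events: bool = False,
                    id_offset: int = 0, arrays: EngineArrays | None = None):
    """Run ``n`` individuals from age 20 to death under a strategy.

    ``strategy`` is ``None``/"none" (no screening), a start age, or a
    "40-GCRSS"-style label.  Identical (n, strategy, parameters, seed)
    give bit-identical results.  Returns (CohortResult, EventLog).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    policy = ScreeningPolicy.parse(strategy)
    arr = arrays if arrays is not None else build_arrays(parameter_set, life_table)
    pv = arr.pv
    coh = _Cohort(n, seed, pv, profile_override, id_offset)
    log = EventLog(enabled=log_events)
    gc_deaths = 0
    other_deaths = 0

    for ai, age in enumerate(_AGES):
        start_alive = coh.alive()
        if not start_alive.any():
            break
        if policy is not None:
            screening_step(coh, int(age), policy, arr, seed, log)
        # state after screening, before transition: the accrual state
        accrual_state = coh.state.copy()
        alive_now = coh.alive()
        idx = np.where(alive_now)[0]
        if idx.size:
            strat = stratum_index(coh.sex[idx], coh.hp[idx].astype(np.int8),
                                  coh.smoke[idx], coh.treat[idx])
            P = arr.M[ai, strat, coh.state[idx]]
            cp = np.cumsum(P, axis=1)
            cp[:, -1] = 1.0
            u = uniform(seed, coh.ids[idx], int(age), _rng.TRANSITION)
            new = (cp > u[:, None]).argmax(axis=1).astype(np.int16)
            old = coh.state[idx]
            # diagnoses: symptomatic surfacing into clinical states
            surfaced = (new >= 9) & (new <= 12) & (old >= 5) & (old <= 8)
            if surfaced.any():
                stages = new[surfaced] - 9
                coh.stage_counts += np.bincount(stages, minlength=4)
                coh.gc_cases += int(surfaced.sum())
                coh.in_program[idx[surfaced]] = False
            died_gc = new == 13
            died_other = new == 14
            if died_gc.any():
                coh.cause[idx[died_gc]] = 1
                gc_deaths += int(died_gc.sum())
            if died_other.any():
                coh.cause[idx[died_other]] = 2
                other_deaths += int(died_other.sum())
            changed = new != old
            coh.years_in_state[idx] = np.where(changed, 0, coh.years_in_state[idx] + 1)
            coh.state[idx] = new
            if log_events and changed.any():
                for j in np.where(changed)[0]:
                    log.append(int(coh.ids[idx[j]]), int(age), "transition",
                               int(old[j]), int(new[j]), 0.0, None)
        # accrual for everyone alive at cycle start (screening deaths included)
        acc = np.where(start_alive)[0]
        died_this_cycle = coh.state[acc] >= 13
        w = np.where(died_this_cycle, 0.5, 1.0)
        util = arr.state_util[accrual_state[acc]]
        coh.life_years[acc] += w
        coh.disc_qaly[acc] += w * util * arr.df[ai]
        cost = arr.state_cost[accrual_state[acc]]
        coh.disc_cost[acc] += cost * arr.df[ai]

    screening_deaths = coh.complication_deaths + coh.surgery_deaths
    assert not coh.alive().any()
    assert gc_deaths + other_deaths + screening_deaths == n, "death conservation"
    result = CohortResult(
        strategy=policy.label if policy is not None else "no screening",
        n=n,
        gc_cases=int(coh.gc_cases),
        gc_deaths=int(gc_deaths),
        other_deaths=int(other_deaths),
        complication_events=int(coh.complication_events),
        complication_deaths=int(coh.complication_deaths + coh.surgery_deaths),
        surgery_deaths=int(coh.surgery_deaths),
        endoscopies=int(coh.n_endoscopy.sum()),
        serology_tests=int(coh.n_serology.sum()),
        stage_counts=tuple(int(c) for c in coh.stage_counts),
        life_years=float(coh.life_years.mean()),
        disc_cost=float(coh.disc_cost.mean()),
        disc_qaly=float(coh.disc_qaly.mean()),
    )
    return result, log


# ---------------------------------------------------------------------------
# deterministic cohort-matrix oracle (no screening)
# ---------------------------------------------------------------------------

@dataclass
class OracleResult:
    """Expected state occupancy by age and the derived epidemiology."""

    ages: np.ndarray
    occupancy: np.ndarray            # (N_AGES, 15), pooled, at cycle start
    diagnoses_by_age_stage: np.ndarray  # (N_AGES, 4) expected per entrant
    gc_deaths: float                 # lifetime expected, per entrant
    lifetime_incidence: float        # diagnosed cases per entrant
    life_years: float                # per entrant (half-year death credit)
    disc_qaly: float
    disc_cost: float
    stage_distribution: np.ndarray   # (4,) shares of lifetime diagnoses

    def prevalence(self, age: int, lesion: HealthState) -> float:
        ai = int(age) - ENTRY_AGE
        occ = self.occupancy[ai]
        alive = occ[:13].sum()
        return float(occ[int(lesion)] / alive) if alive > 0 else 0.0

    def incidence_rate(self, age: int) -> float:
        ai = int(age) - ENTRY_AGE
        alive = self.occupancy[ai, :13].sum()
        return float(self.diagnoses_by_age_stage[ai].sum() / alive) if alive > 0 else 0.0


def cohort_matrix_oracle(parameter_set: ParameterSet, life_table: LifeTable,
                         strategy="none", profile_override=None,
                         arrays: EngineArrays | None = None) -> OracleResult:
    """Exact expectations by forward matrix multiplication over strata.

    Screening is history-dependent, so only the no-screening case is
    supported; the microsimulation and this oracle share the transition
    kernels, so they differ only by sampling noise.
    """
    if ScreeningPolicy.parse(strategy) is not None:
        raise ValueError("the matrix oracle supports the no-screening strategy only")
    arr = arrays if arrays is not None else build_arrays(parameter_set, life_table)
    pv = arr.pv

    # stratum weights (treat level fixed at 0 without screening)
    weights = {}
    p_hp = pv["hp_prevalence"]
    if profile_override and "hp" in profile_override:
        p_hp = 1.0 if profile_override["hp"] else 0.0
    for sex in (0, 1):
        w_sex = pv["male_fraction"] if sex == 0 else 1.0 - pv["male_fraction"]
        if profile_override and "sex" in profile_override:
            w_sex = 1.0 if (profile_override["sex"] == "male") == (sex == 0) else 0.0
        sp = pv["smoking_prev_male"] if sex == 0 else pv["smoking_prev_female"]
        hv = pv["heavy_smoker_fraction"]
        w_smoke = {0: 1.0 - sp, 1: sp * (1.0 - hv), 2: sp * hv}
        if profile_override and "smoking" in profile_override:
            lv = profile_override["smoking"]
            if lv == "current":
                w_smoke = {0: 0.0, 1: 1.0 - hv, 2: hv}
            else:
                w_smoke = {k: float(k == _SMOKE_CODE[lv]) for k in (0, 1, 2)}
        for hp in (0, 1):
            w_hp = p_hp if hp else 1.0 - p_hp
            for smoke in (0, 1, 2):
                w = w_sex * w_hp * w_smoke[smoke]
                if w > 0:
                    weights[int(stratum_index(sex, hp, smoke, 0))] = w

    occ = {s: np.zeros(N_STATES) for s in weights}
    for s in occ:
        occ[s][0] = 1.0
    occupancy = np.zeros((N_AGES, N_STATES))
    diagnoses = np.zeros((N_AGES, 4))
    gc_deaths = 0.0
    life_years = 0.0
    disc_qaly = 0.0
    disc_cost = 0.0

    for ai in range(N_AGES):
        for s, w in weights.items():
            occupancy[ai] += w * occ[s]
        pooled = occupancy[ai]
        alive = pooled[:13].sum()
        deaths_this = 0.0
        util_weighted_deaths = 0.0
        for s, w in weights.items():
            K = arr.M[ai, s]
            o = occ[s]
            death_prob = K[:, 13] + K[:, 14]
            d = float((o[:13] * death_prob[:13]).sum())
            deaths_this += w * d
            util_weighted_deaths += w * float(
                (o[:13] * death_prob[:13] * arr.state_util[:13]).sum())
            for k in range(4):
                diagnoses[ai, k] += w * float(o[5 + k] * K[5 + k, 9 + k])
            gc_deaths += w * float((o[:13] * K[:13, 13]).sum())
            occ[s] = o @ K
        life_years += alive - 0.5 * deaths_this
        disc_qaly += arr.df[ai] * (
            float((pooled[:13] * arr.state_util[:13]).sum()) - 0.5 * util_weighted_deaths)
        disc_cost += arr.df[ai] * float((pooled * arr.state_cost).sum())

    total_diag = diagnoses.sum()
    stage = diagnoses.sum(axis=0) / total_diag if total_diag > 0 else np.zeros(4)
    return OracleResult(
        ages=_AGES.copy(),
        occupancy=occupancy,
        diagnoses_by_age_stage=diagnoses,
        gc_deaths=float(gc_deaths),
        lifetime_incidence=float(total_diag),
        life_years=float(life_years),
        disc_qaly=float(disc_qaly),
        disc_cost=float(disc_cost),
        stage_distribution=stage,
    )
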