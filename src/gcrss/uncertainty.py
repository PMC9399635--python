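"""Sensitivity analyses: one-way (tornado), probabilistic (PSA + CEAC),
subgroup and scenario runners.

All comparisons use common random numbers: the same cohort seed (hence
the same individuals and per-individual substreams) under every
parameter value and strategy, so differences reflect the perturbation,
not sampling noise.  PSA distributions are beta for probabilities and
utilities, gamma for costs, lognormal for relative risks, fitted by
moments from (base, low, high) with sd = (high - low)/3.92.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .health_econ import WTP_3X_GDP, compute_icer
from .model_params import (
    LifeTable,
    ParameterSet,
    default_parameter_set,
    generate_life_table,
)
from .natural_history import build_arrays, simulate_cohort

__all__ = [
    "EngineConfig",
    "PsaDraw",
    "Ceac",
    "one_way",
    "tornado",
    "sample_parameter_set",
    "run_psa",
    "run_subgroup",
    "run_scenario",
    "ALL_STRATEGIES",
]

ALL_STRATEGIES = ("none", 40, 45, 50, 55, 60, 65, 70)


@dataclass
class EngineConfig:
    """Shared settings for sensitivity runs."""

    parameter_set: ParameterSet = field(default_factory=default_parameter_set)
    life_table: LifeTable | None = None
    n: int = 20_000
    seed: int = 0
    strategy: object = 40        # strategy under study
    reference: object = "none"

    def lt(self) -> LifeTable:
        return self.life_table if self.life_table is not None \
            else generate_life_table(self.seed)


def _icer_pair(ps: ParameterSet, cfg: EngineConfig):
    lt = cfg.lt()
    arr = build_arrays(ps, lt)
    res, _ = simulate_cohort(cfg.n, cfg.strategy, ps, lt, cfg.seed, arrays=arr)
    ref, _ = simulate_cohort(cfg.n, cfg.reference, ps, lt, cfg.seed, arrays=arr)
    return compute_icer(res.disc_cost, res.disc_qaly, ref.disc_cost, ref.disc_qaly), res, ref


def one_way(parameter_name: str, config: EngineConfig | None = None):
    """ICER of the studied strategy vs reference at the parameter's low and
    high bound, common random numbers throughout."""
    cfg = config if config is not None else EngineConfig()
    ps = cfg.parameter_set
    if parameter_name not in ps:
        raise KeyError(f"unknown parameter {parameter_name!r}")
    prm = ps.params[parameter_name]
    out = []
    for v in (prm.low, prm.high):
        icer, _, _ = _icer_pair(ps.with_overrides({parameter_name: v}), cfg)
        out.append(icer)
    return tuple(out)


def tornado(config: EngineConfig | None = None, parameter_names=None) -> pd.DataFrame:
    """One-way ICER spans for every varied parameter, widest first."""
    cfg = config if config is not None else EngineConfig()
    ps = cfg.parameter_set
    names = parameter_names if parameter_names is not None else [
        k for k, p in ps.params.items() if p.high > p.low]
    base_icer, _, _ = _icer_pair(ps, cfg)
    rows = []
    for name in names:
        lo, hi = one_way(name, cfg)
        lo_v = lo if isinstance(lo, float) else np.nan
        hi_v = hi if isinstance(hi, float) else np.nan
        rows.append({"parameter": name, "icer_low": lo_v, "icer_high": hi_v,
                     "span": abs(hi_v - lo_v)})
    df = pd.DataFrame(rows).sort_values("span", ascending=False).reset_index(drop=True)
    df.attrs["base_icer"] = base_icer
    return df


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass
class PsaDraw:
    values: dict                  # sampled parameter values
    results: dict                 # strategy -> (cost, qaly)


@dataclass
class Ceac:
    """P(strategy is cost-effective) on a WTP grid; rows sum to one."""

    table: pd.DataFrame           # columns: wtp, strategy, probability

    def at(self, wtp: float, strategy) -> float:
        t = self.table
        row = t[(t.wtp == wtp) & (t.strategy == _label(strategy))]
        return float(row.probability.iloc[0])


def _label(strategy) -> str:
    return "no screening" if strategy in (None, "none", "no screening") \
        else f"{int(str(strategy).split('-')[0])}-GCRSS"


def sample_parameter_set(ps: ParameterSet, rng: np.random.Generator,
                         shrink: float = 1.0) -> ParameterSet:
    """One PSA draw; ``shrink`` < 1 narrows every distribution (limit checks)."""
    values = {}
    for name, prm in ps.params.items():
        if prm.dist == "fixed" or prm.high == prm.low:
            continue
        sd = (prm.high - prm.low) / 3.92 * shrink
        m = prm.base
        if sd <= 0:
            continue
        if prm.dist == "beta":
            v = m * (1 - m) / sd**2 - 1
            if v <= 0 or not (0 < m < 1):
                continue
            values[name] = float(np.clip(rng.beta(m * v, (1 - m) * v), 0.0, 1.0))
        elif prm.dist == "gamma":
            shape = (m / sd) ** 2
            values[name] = float(rng.gamma(shape, sd**2 / m))
        elif prm.dist == "lognormal":
            sigma = np.log(prm.high / prm.low) / 3.92 * shrink
            values[name] = float(rng.lognormal(np.log(m) - sigma**2 / 2, sigma))
        else:  # pragma: no cover
            raise ValueError(f"invalid distribution for {name}")
    return ps.with_overrides(values)


def run_psa(n_draws: int, n_individuals_per_draw: int = 10_000, seed: int = 0,
            parameter_set: ParameterSet | None = None,
            life_table: LifeTable | None = None,
            strategies=ALL_STRATEGIES, wtp_grid=None, shrink: float = 1.0):
    """Sample the registry ``n_draws`` times, run every strategy per draw
    with common random numbers, and build the CEAC by highest net monetary
    benefit (ties toward lower cost).  Deterministic for a fixed seed."""
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    ps = parameter_set if parameter_set is not None else default_parameter_set()
    lt = life_table if life_table is not None else generate_life_table(seed)
    grid = np.asarray(wtp_grid if wtp_grid is not None
                      else np.arange(0.0, 50_001.0, 2_500.0))
    rng = np.random.default_rng(seed)
    labels = [_label(s) for s in strategies]
    draws = []
    wins = np.zeros((len(grid), len(strategies)))
    for _ in range(n_draws):
        ps_i = sample_parameter_set(ps, rng, shrink)
        arr = build_arrays(ps_i, lt)
        results = {}
        costs = np.empty(len(strategies))
        qalys = np.empty(len(strategies))
        for j, s in enumerate(strategies):
            res, _ = simulate_cohort(n_individuals_per_draw, s, ps_i, lt, seed,
                                     arrays=arr)
            results[labels[j]] = (res.disc_cost, res.disc_qaly)
            costs[j], qalys[j] = res.disc_cost, res.disc_qaly
        draws.append(PsaDraw(ps_i.values(), results))
        nmb = qalys[None, :] * grid[:, None] - costs[None, :]
        # ties toward lower cost: subtract an infinitesimal cost ranking
        nmb -= 1e-9 * np.argsort(np.argsort(costs))[None, :]
        wins[np.arange(len(grid)), nmb.argmax(axis=1)] += 1.0
    prob = wins / n_draws
    rows = [{"wtp": float(grid[i]), "strategy": labels[j],
             "probability": float(prob[i, j])}
            for i in range(len(grid)) for j in range(len(strategies))]
    return draws, Ceac(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# subgroups and scenarios
# ---------------------------------------------------------------------------

_SUBGROUPS = {
    "hp_pos": {"hp": True},
    "hp_neg": {"hp": False},
    "never": {"smoking": "never"},
    "light": {"smoking": "light"},
    "heavy": {"smoking": "heavy"},
}


def run_subgroup(subgroup: str, strategies=("none", 40), seed: int = 0,
                 parameter_set: ParameterSet | None = None,
                 life_table: LifeTable | None = None, n: int = 20_000) -> dict:
    """Re-run strategies with the cohort's risk profile forced to a subgroup."""
    if subgroup not in _SUBGROUPS:
        raise ValueError(f"unknown subgroup {subgroup!r}; one of {sorted(_SUBGROUPS)}")
    ps = parameter_set if parameter_set is not None else default_parameter_set()
    lt = life_table if life_table is not None else generate_life_table(seed)
    arr = build_arrays(ps, lt)
    out = {}
    for s in strategies:
        res, _ = simulate_cohort(n, s, ps, lt, seed,
                                 profile_override=_SUBGROUPS[subgroup], arrays=arr)
        out[_label(s)] = res
    return out


def run_scenario(scenario: str, config: EngineConfig | None = None,
                 rr_grid=None) -> dict:
    """Named scenario analyses.

    ``healthy_china_2030``: Hp and smoking prevalence lowered to 20%; reports
    the 40-GCRSS vs no-screening ICER against the 3x-GDP threshold.
    ``surgery_rr_sweep``: sweeps the post-surgery progression relative risk
    and reports the ICER at each value plus the threshold crossing point.
    """
    cfg = config if config is not None else EngineConfig()
    if scenario == "healthy_china_2030":
        ps = default_parameter_set("healthy_china_2030")
        cfg2 = EngineConfig(ps, cfg.life_table, cfg.n, cfg.seed,
                            cfg.strategy, cfg.reference)
        icer, res, ref = _icer_pair(ps, cfg2)
        return {
            "scenario": scenario,
            "icer": icer if isinstance(icer, float) else None,
            "verdict": icer if isinstance(icer, str) else None,
            "wtp_threshold": WTP_3X_GDP,
            "below_threshold": isinstance(icer, float) and icer < WTP_3X_GDP,
            "gc_cases": res.gc_cases, "gc_cases_reference": ref.gc_cases,
        }
    if scenario == "surgery_rr_sweep":
        grid = np.asarray(rr_grid if rr_grid is not None
                          else np.arange(0.5, 1.01, 0.1))
        icers = []
        for rr in grid:
            ps = cfg.parameter_set.with_overrides(
                {"rr_progression_after_surgery": float(rr)})
            icer, _, _ = _icer_pair(ps, cfg)
            icers.append(icer if isinstance(icer, float) else np.nan)
        icers = np.asarray(icers, dtype=float)
        above = icers > WTP_3X_GDP
        crossing = float(grid[above.argmax()]) if above.any() else None
        return {
            "scenario": scenario,
            "rr_grid": [float(g) for g in grid],
            "icers": [float(i) for i in icers],
            "wtp_threshold": WTP_3X_GDP,
            "crossing_rr": crossing,
        }
    raise ValueError(f"unknown scenario {scenario!r}")
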