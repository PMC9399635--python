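"""Fitting the unknown progression probabilities to epidemiologic targets.

The loss compares deterministic cohort-oracle outputs (lesion prevalence
by age, annual GC incidence by age, clinical stage distribution) with the
targets as a weighted sum of squared relative deviations.  The search is
multi-start: Latin-hypercube samples over the parameter box, each refined
by Nelder-Mead in log-parameter space.  The oracle keeps every loss
evaluation deterministic; microsimulation enters only in the external
validation of the fitted set (lifetime-incidence relative risks for Hp
infection and smoking).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import qmc

from .model_params import (
    CALIBRATED_PARAMS,
    CalibrationTargets,
    HealthState,
    LifeTable,
    ParameterSet,
    default_parameter_set,
    generate_life_table,
)
from .natural_history import cohort_matrix_oracle, simulate_cohort

__all__ = [
    "SearchConfig",
    "CalibrationResult",
    "calibration_loss",
    "calibrate",
    "validate",
]


@dataclass
class SearchConfig:
    """Bounds and budget for the multi-start search."""

    rel_bounds: float = 0.5          # box half-width around the base values
    n_starts: int = 8                # Latin-hypercube starting points
    max_iter: int = 300              # Nelder-Mead iterations per start
    bounds: dict = field(default_factory=dict)  # per-parameter overrides
    param_names: tuple = CALIBRATED_PARAMS

    def box(self, base: ParameterSet):
        lo, hi = [], []
        for name in self.param_names:
            b = base.value(name)
            l, h = self.bounds.get(name, (b * (1 - self.rel_bounds),
                                          b * (1 + self.rel_bounds)))
            if base.params[name].dist == "beta":
                h = min(h, 1.0)
            lo.append(max(l, 1e-8))
            hi.append(h)
        return np.array(lo), np.array(hi)


@dataclass
class CalibrationResult:
    accepted: list            # [(values dict, loss)], loss-ascending
    best_values: dict
    best_params: ParameterSet
    best_loss: float
    table: pd.DataFrame       # target, fitted, deviation
    rr_hp: float
    rr_smoking: float

    def report_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _target_rows(targets: CalibrationTargets):
    rows = []
    for r in targets.lesion_prevalence.itertuples():
        rows.append(("prevalence", (int(r.age), HealthState[r.lesion]),
                     r.value, r.tol, r.weight))
    for r in targets.gc_incidence.itertuples():
        rows.append(("incidence", int(r.age), r.value, r.tol, r.weight))
    for r in targets.stage_distribution.itertuples():
        rows.append(("stage", int(r.stage), r.value, r.tol, r.weight))
    return rows


def _model_values(oracle, rows):
    out = []
    for kind, key, *_ in rows:
        if kind == "prevalence":
            out.append(oracle.prevalence(key[0], key[1]))
        elif kind == "incidence":
            out.append(oracle.incidence_rate(key))
        else:
            out.append(float(oracle.stage_distribution[key - 1]))
    return np.array(out)


def calibration_loss(parameter_set: ParameterSet, targets: CalibrationTargets,
                     life_table: LifeTable | None = None) -> float:
    """Weighted sum of squared relative deviations, zero iff all targets hit."""
    lt = life_table if life_table is not None else generate_life_table(0)
    rows = _target_rows(targets)
    oracle = cohort_matrix_oracle(parameter_set, lt)
    model = _model_values(oracle, rows)
    tgt = np.array([r[2] for r in rows])
    w = np.array([r[4] for r in rows])
    dev = (model - tgt) / np.maximum(tgt, 1e-6)
    return float(np.sum(w * dev**2))


def calibrate(targets: CalibrationTargets, search_config: SearchConfig | None = None,
              seed: int = 0, life_table: LifeTable | None = None,
              base: ParameterSet | None = None) -> CalibrationResult:
    """Multi-start Latin-hypercube + Nelder-Mead fit; deterministic per seed.

    Raises ``RuntimeError`` when no candidate brings every target within
    its stated tolerance.
    """
    cfg = search_config if search_config is not None else SearchConfig()
    lt = life_table if life_table is not None else generate_life_table(0)
    base = base if base is not None else default_parameter_set()
    names = list(cfg.param_names)
    lo, hi = cfg.box(base)
    rows = _target_rows(targets)
    tgt = np.array([r[2] for r in rows])
    w = np.array([r[4] for r in rows])
    tol = np.array([r[3] for r in rows])

    def assemble(x) -> ParameterSet:
        x = np.clip(x, lo, hi)
        return base.with_overrides(dict(zip(names, x)))

    def loss_of(x):
        oracle = cohort_matrix_oracle(assemble(x), lt)
        dev = (_model_values(oracle, rows) - tgt) / np.maximum(tgt, 1e-6)
        return float(np.sum(w * dev**2)), dev

    def f(z):
        x = np.exp(z)
        penalty = float(np.sum(np.clip(x - hi, 0, None) ** 2)
                        + np.sum(np.clip(lo - x, 0, None) ** 2)) * 1e4
        return loss_of(x)[0] + penalty

    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    starts = lo + sampler.random(cfg.n_starts) * (hi - lo)
    accepted = []
    best_x, best_loss = None, np.inf
    for x0 in starts:
        if cfg.max_iter > 0:
            res = minimize(f, np.log(x0), method="Nelder-Mead",
                           options={"maxiter": cfg.max_iter, "xatol": 1e-4,
                                    "fatol": 1e-10})
            x = np.clip(np.exp(res.x), lo, hi)
        else:
            x = x0
        loss, dev = loss_of(x)
        if np.all(np.abs(dev) <= tol):
            accepted.append((dict(zip(names, x)), loss))
        if loss < best_loss:
            best_x, best_loss = x, loss

    if not accepted:
        raise RuntimeError(
            f"no parameter set met every target tolerance (best loss {best_loss:.4g})")
    accepted.sort(key=lambda t: t[1])
    best_values = dict(zip(names, best_x))
    best_params = assemble(best_x)
    oracle = cohort_matrix_oracle(best_params, lt)
    model = _model_values(oracle, rows)
    table = pd.DataFrame({
        "kind": [r[0] for r in rows],
        "key": [str(r[1]) for r in rows],
        "target": tgt,
        "fitted": model,
        "deviation": (model - tgt) / np.maximum(tgt, 1e-6),
    })
    rr_hp, rr_smoking = validate(best_params, lt, method="oracle")
    return CalibrationResult(accepted, best_values, best_params, best_loss,
                             table, rr_hp, rr_smoking)


def validate(parameter_set: ParameterSet, life_table: LifeTable | None = None,
             n: int = 40_000, seed: int = 0, method: str = "micro"):
    """Lifetime GC-incidence relative risks: Hp+ vs Hp-, current vs never
    smokers.  ``method='micro'`` simulates exposure-forced cohorts (common
    random numbers); ``'oracle'`` uses exact stratum expectations."""
    lt = life_table if life_table is not None else generate_life_table(0)
    overrides = {
        "hp_pos": {"hp": True}, "hp_neg": {"hp": False},
        "smoker": {"smoking": "current"}, "never": {"smoking": "never"},
    }
    inc = {}
    for key, ov in overrides.items():
        if method == "oracle":
            inc[key] = cohort_matrix_oracle(parameter_set, lt,
                                            profile_override=ov).lifetime_incidence
        else:
            res, _ = simulate_cohort(n, None, parameter_set, lt, seed,
                                     profile_override=ov)
            if res.gc_cases == 0:
                raise RuntimeError(f"no GC cases in stratum {key!r}")
            inc[key] = res.gc_cases / n
    return inc["hp_pos"] / inc["hp_neg"], inc["smoker"] / inc["never"]
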