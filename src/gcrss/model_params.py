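"""Parameter registry, life table, and synthetic calibration targets.

The model follows a 15-state natural history of gastric cancer (GC):
a precancerous cascade (normal mucosa -> non-atrophic gastritis ->
atrophic gastritis -> intestinal metaplasia -> dysplasia), four
preclinical (asymptomatic, screen-detectable) cancer stages, four
clinical (symptomatically diagnosed) stages, and two absorbing death
states (GC death, other-cause death).

Every model input lives in a single registry (:class:`ParameterSet`)
carrying a base value, a plausible low/high range (default base x
[0.8, 1.2]) and a probabilistic-sensitivity-analysis distribution
family.  The life table and the calibration targets are synthetic:
the life table is Gompertz-Makeham shaped and tuned so that life
expectancy at the age-20 model entry is in the mid-50s, and targets
are produced by running the deterministic cohort engine with a known
"truth" parameter set, so that calibration can be validated as a
parameter-recovery exercise.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import uniform

__all__ = [
    "HealthState",
    "RiskProfile",
    "Param",
    "ParameterSet",
    "LifeTable",
    "CalibrationTargets",
    "default_parameter_set",
    "generate_life_table",
    "generate_calibration_targets",
    "AGE_BANDS",
    "CALIBRATED_PARAMS",
]


class HealthState(enum.IntEnum):
    """The 15 health states; the two death states are absorbing."""

    Normal = 0
    NonAtrophicGastritis = 1
    AtrophicGastritis = 2
    IntestinalMetaplasia = 3
    Dysplasia = 4
    PreclinicalGC_I = 5
    PreclinicalGC_II = 6
    PreclinicalGC_III = 7
    PreclinicalGC_IV = 8
    ClinicalGC_I = 9
    ClinicalGC_II = 10
    ClinicalGC_III = 11
    ClinicalGC_IV = 12
    DeathGC = 13
    DeathOther = 14


# serology "atrophy status" is positive for atrophic mucosa onward,
# including occult preclinical cancer (the lesion sits in atrophic mucosa)
ATROPHY_STATES = frozenset(
    {
        HealthState.AtrophicGastritis,
        HealthState.IntestinalMetaplasia,
        HealthState.Dysplasia,
        HealthState.PreclinicalGC_I,
        HealthState.PreclinicalGC_II,
        HealthState.PreclinicalGC_III,
        HealthState.PreclinicalGC_IV,
    }
)
PRECLINICAL_STATES = (
    HealthState.PreclinicalGC_I,
    HealthState.PreclinicalGC_II,
    HealthState.PreclinicalGC_III,
    HealthState.PreclinicalGC_IV,
)
CLINICAL_STATES = (
    HealthState.ClinicalGC_I,
    HealthState.ClinicalGC_II,
    HealthState.ClinicalGC_III,
    HealthState.ClinicalGC_IV,
)
DEAD_STATES = (HealthState.DeathGC, HealthState.DeathOther)

ENTRY_AGE = 20
MAX_AGE = 100

# 5-year age bands 20-24 ... 80-84, 85+
AGE_BANDS = tuple(range(20, 90, 5))

# fixed age shape on the onset (Normal -> gastritis) transition:
# gastric mucosal injury accumulates with age and saturates late in life
_AGE_MULT = np.array(
    [0.40, 0.55, 0.70, 0.85, 1.00, 1.15, 1.30, 1.40, 1.50, 1.55, 1.60, 1.60, 1.60, 1.60]
)


def age_band_index(age) -> np.ndarray:
    return np.minimum(np.maximum((np.asarray(age) - 20) // 5, 0), len(AGE_BANDS) - 1)


@dataclass
class RiskProfile:
    """Fixed individual risk factors (Hp status may be cleared by therapy)."""

    sex: str  # "male" | "female"
    hp_infected: bool
    smoking: str  # "never" | "light" (<10 cig/day) | "heavy" (>=10 cig/day)

    def __post_init__(self):
        if self.sex not in ("male", "female"):
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.smoking not in ("never", "light", "heavy"):
            raise ValueError(f"unknown smoking level {self.smoking!r}")


@dataclass
class Param:
    """One model input: base value, plausible range, PSA family."""

    base: float
    low: float
    high: float
    dist: str  # "beta" | "gamma" | "lognormal" | "fixed"

    def __post_init__(self):
        if not (self.low <= self.base <= self.high):
            raise ValueError(f"require low <= base <= high, got {self}")
        if self.dist not in ("beta", "gamma", "lognormal", "fixed"):
            raise ValueError(f"unknown distribution {self.dist!r}")


def _prob(base, low=None, high=None):
    low = 0.8 * base if low is None else low
    high = min(1.2 * base, 1.0) if high is None else high
    return Param(base, low, high, "beta")


def _cost(base):
    return Param(base, 0.8 * base, 1.2 * base, "gamma")


def _rr(base, low=None, high=None):
    return Param(base, 0.8 * base if low is None else low,
                 1.2 * base if high is None else high, "lognormal")


def _util(base):
    return Param(base, 0.8 * base, min(1.2 * base, 1.0), "beta")


def _fixed(base):
    return Param(base, base, base, "fixed")


# parameters the calibration routine treats as free
CALIBRATED_PARAMS = (
    "p_normal_nag",
    "p_nag_ag",
    "p_ag_im",
    "p_im_dys",
    "p_dys_pre1",
    "advance_scale",
    "surface_scale",
)

_SMOKING_LEVELS = ("never", "light", "heavy")


def _default_registry() -> dict:
    """The synthetic truth registry (annual probabilities, 2021 USD).

    Transition bases were tuned against the deterministic cohort engine so
    the unscreened cohort reproduces the epidemiology the model is built
    around: ~11.6% lifetime GC incidence, ~10,000 GC deaths per 100,000,
    an advanced-stage-dominated clinical stage distribution, a lifetime
    incidence relative risk near 4.3 for Hp infection and near 1.7 for
    current smoking.
    """
    p: dict[str, Param] = {}

    # --- precancerous cascade (annual transition probabilities) ---
    p["p_normal_nag"] = _prob(0.097)    # onset, scaled by the age shape
    p["p_nag_ag"] = _prob(0.014)        # multiplied by rr_hp_atrophy when Hp+
    p["p_ag_im"] = _prob(0.090)
    p["p_im_dys"] = _prob(0.012)        # multiplied by the smoking RR
    p["p_dys_pre1"] = _prob(0.050)      # multiplied by post-treatment RR

    # preclinical stage advance and symptomatic surfacing
    p["p_advance_1"] = _prob(0.55)
    p["p_advance_2"] = _prob(0.65)
    p["p_advance_3"] = _prob(0.75)
    p["p_surface_1"] = _prob(0.08)
    p["p_surface_2"] = _prob(0.20)
    p["p_surface_3"] = _prob(0.45)
    p["p_surface_4"] = _prob(0.75)
    # global scales searched by calibration (structure, not PSA inputs)
    p["advance_scale"] = _fixed(1.0)
    p["surface_scale"] = _fixed(1.0)

    # --- risk modifiers ---
    p["rr_hp_atrophy"] = _rr(12.0, 6.0, 18.0)
    p["rr_smoking_light"] = _rr(1.7)
    p["rr_smoking_heavy"] = _rr(2.2)

    # --- clinical GC annual excess mortality by stage ---
    p["gc_mortality_1"] = _prob(0.06)
    p["gc_mortality_2"] = _prob(0.20)
    p["gc_mortality_3"] = _prob(0.48)
    p["gc_mortality_4"] = _prob(0.85)

    # --- cohort composition ---
    p["hp_prevalence"] = _prob(0.67)
    p["smoking_prev_male"] = _prob(0.64)
    p["smoking_prev_female"] = _prob(0.34)
    p["heavy_smoker_fraction"] = _prob(0.50)
    p["male_fraction"] = _fixed(0.50)

    # --- test characteristics ---
    p["sens_hp_serology"] = _prob(0.92)
    p["spec_hp_serology"] = _prob(0.90)
    p["sens_atrophy_serology"] = _prob(0.75)
    p["spec_atrophy_serology"] = _prob(0.85)
    p["sens_endo_dysplasia"] = _prob(0.90)
    p["sens_endo_pre1"] = _prob(0.85)
    p["sens_endo_pre2"] = _prob(0.93)
    p["sens_endo_pre3"] = _prob(0.96)
    p["sens_endo_pre4"] = _prob(0.98)
    p["spec_endoscopy"] = _prob(0.98)

    # --- treatment ---
    p["esd_fraction_dysplasia"] = _prob(0.80)
    p["esd_fraction_stage1"] = _prob(0.50)
    p["p_bleeding_esd"] = _prob(0.040)
    p["p_perforation_esd"] = _prob(0.010)
    p["p_bleeding_surgery"] = _prob(0.080)
    p["p_perforation_surgery"] = _prob(0.030)
    p["p_complication_fatal"] = _prob(0.030)
    p["p_surgery_death"] = _prob(0.005)
    p["rr_progression_after_esd"] = _rr(0.20)
    p["rr_progression_after_surgery"] = _rr(0.50)
    p["hp_eradication_success"] = _prob(0.85)

    # --- direct medical costs, 2021 USD (1 USD = 6.4856 RMB) ---
    p["cost_serology"] = _cost(9.0)
    p["cost_endoscopy"] = _cost(45.0)
    p["cost_biopsy"] = _cost(25.0)
    p["cost_hp_therapy"] = _cost(55.0)
    p["cost_esd"] = _cost(2300.0)
    p["cost_surgery"] = _cost(5800.0)
    p["cost_bleeding"] = _cost(450.0)
    p["cost_perforation"] = _cost(1400.0)
    p["cost_gc_stage1"] = _cost(3200.0)
    p["cost_gc_stage2"] = _cost(5200.0)
    p["cost_gc_stage3"] = _cost(7800.0)
    p["cost_gc_stage4"] = _cost(9500.0)

    # --- utilities (QALY weights) ---
    p["utility_noncancer"] = _fixed(1.0)
    p["utility_stage1"] = _util(0.88)
    p["utility_stage2"] = _util(0.68)
    p["utility_stage3"] = _util(0.50)
    p["utility_stage4"] = _util(0.30)

    p["discount_rate"] = _fixed(0.05)
    return p


@dataclass
class ParameterSet:
    """Registry of every model input, with range and PSA distribution."""

    params: dict = field(default_factory=_default_registry)

    # -- access ----------------------------------------------------------
    def value(self, name: str) -> float:
        return self.params[name].base

    def values(self) -> dict:
        return {k: v.base for k, v in self.params.items()}

    def __contains__(self, name: str) -> bool:
        return name in self.params

    def with_overrides(self, overrides: dict) -> "ParameterSet":
        """New set with selected base values replaced (ranges follow the
        default base x [0.8, 1.2] rule unless the old range still brackets
        the new base)."""
        new = {k: Param(v.base, v.low, v.high, v.dist) for k, v in self.params.items()}
        for k, val in overrides.items():
            old = new[k]
            lo, hi = old.low, old.high
            if not (lo <= val <= hi):
                lo, hi = sorted((0.8 * val, 1.2 * val))
                if old.dist == "beta":
                    hi = min(hi, 1.0)
            new[k] = Param(val, min(lo, val), max(hi, val), old.dist)
        return ParameterSet(new)

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        for name, prm in self.params.items():
            if prm.dist == "beta" and not (0.0 <= prm.base <= 1.0):
                raise ValueError(f"{name}: probability/utility outside [0,1]")
            if prm.dist == "gamma" and prm.base < 0:
                raise ValueError(f"{name}: negative cost")
            if prm.dist == "lognormal" and prm.base <= 0:
                raise ValueError(f"{name}: non-positive relative risk")
            if not (prm.low <= prm.base <= prm.high):
                raise ValueError(f"{name}: range does not bracket base")

    def smoking_rr(self, level: str) -> float:
        return {"never": 1.0,
                "light": self.value("rr_smoking_light"),
                "heavy": self.value("rr_smoking_heavy")}[level]

    def transition_table(self) -> dict:
        """(from-state, to-state, age-band) -> annual base probability.

        Risk-factor multipliers (Hp, smoking, post-treatment) are not
        folded in; the engine applies them on the probability scale.
        """
        adv = self.value("advance_scale")
        srf = self.value("surface_scale")
        edges = {
            (HealthState.Normal, HealthState.NonAtrophicGastritis): ("p_normal_nag", _AGE_MULT),
            (HealthState.NonAtrophicGastritis, HealthState.AtrophicGastritis): ("p_nag_ag", None),
            (HealthState.AtrophicGastritis, HealthState.IntestinalMetaplasia): ("p_ag_im", None),
            (HealthState.IntestinalMetaplasia, HealthState.Dysplasia): ("p_im_dys", None),
            (HealthState.Dysplasia, HealthState.PreclinicalGC_I): ("p_dys_pre1", None),
        }
        table = {}
        for (a, b), (name, mult) in edges.items():
            for i, band in enumerate(AGE_BANDS):
                m = 1.0 if mult is None else float(mult[i])
                table[(a, b, band)] = self.value(name) * m
        for k in range(1, 4):
            src, dst = PRECLINICAL_STATES[k - 1], PRECLINICAL_STATES[k]
            for band in AGE_BANDS:
                table[(src, dst, band)] = min(adv * self.value(f"p_advance_{k}"), 1.0)
        for k in range(1, 5):
            src, dst = PRECLINICAL_STATES[k - 1], CLINICAL_STATES[k - 1]
            for band in AGE_BANDS:
                table[(src, dst, band)] = min(srf * self.value(f"p_surface_{k}"), 1.0)
        return table

    # -- serialization ---------------------------------------------------
    def to_json(self, path=None) -> str:
        payload = {k: asdict(v) for k, v in self.params.items()}
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "ParameterSet":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        payload = json.loads(text)
        return cls({k: Param(**v) for k, v in payload.items()})


def default_parameter_set(scenario: str = "baseline") -> ParameterSet:
    """Complete registry for a named scenario.

    ``baseline`` uses the Chinese epidemiologic setting (67% Hp prevalence,
    smoking 64%/34% in men/women); ``healthy_china_2030`` lowers Hp and
    both-sex smoking prevalence to the 20% policy goal.
    """
    ps = ParameterSet()
    if scenario == "baseline":
        pass
    elif scenario == "healthy_china_2030":
        ps = ps.with_overrides(
            {"hp_prevalence": 0.20, "smoking_prev_male": 0.20, "smoking_prev_female": 0.20}
        )
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    ps.validate()
    return ps


# ---------------------------------------------------------------------------
# life table
# ---------------------------------------------------------------------------

@dataclass
class LifeTable:
    """Annual all-cause (non-GC) death probability by single year of age and sex."""

    qx_male: np.ndarray   # length 101, ages 0..100
    qx_female: np.ndarray

    def __post_init__(self):
        self.qx_male = np.asarray(self.qx_male, dtype=float)
        self.qx_female = np.asarray(self.qx_female, dtype=float)
        for q in (self.qx_male, self.qx_female):
            if q.shape != (MAX_AGE + 1,):
                raise ValueError("life table must cover ages 0..100")
            if np.any((q < 0) | (q > 1)):
                raise ValueError("death probabilities outside [0,1]")

    def qx(self, age, sex_code) -> np.ndarray:
        """Vectorized lookup; sex_code 0 = male, 1 = female."""
        age = np.minimum(np.asarray(age, dtype=int), MAX_AGE)
        return np.where(np.asarray(sex_code) == 0, self.qx_male[age], self.qx_female[age])

    def expectation_from(self, age: int, male_fraction: float = 0.5) -> float:
        """Expected remaining years from ``age`` (half-year death-cycle credit)."""
        total = 0.0
        for sex, w in ((0, male_fraction), (1, 1.0 - male_fraction)):
            q = self.qx_male if sex == 0 else self.qx_female
            s, years = 1.0, 0.0
            for a in range(age, MAX_AGE + 1):
                qa = q[a] if a < MAX_AGE else 1.0
                years += s * (1.0 - 0.5 * qa)
                s *= 1.0 - qa
            total += w * years
        return total

    def to_csv(self, path) -> None:
        rows = [(a, s, (self.qx_male if s == "male" else self.qx_female)[a])
                for s in ("male", "female") for a in range(MAX_AGE + 1)]
        pd.DataFrame(rows, columns=["age", "sex", "qx"]).to_csv(
            path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        df = pd.read_csv(path, float_precision="round_trip")
        m = df[df.sex == "male"].sort_values("age").qx.to_numpy()
        f = df[df.sex == "female"].sort_values("age").qx.to_numpy()
        return cls(m, f)


def generate_life_table(seed: int) -> LifeTable:
    """Synthetic Gompertz-Makeham life table, one per seed.

    q(a) = c + A exp(B a), with sex-specific constants jittered +/-2% by the
    seed.  Constants are set so pooled life expectancy at the age-20 model
    entry sits in the mid-50s, matching an East-Asian population with
    moderate background mortality.
    """
    base = {
        0: (4.4e-05, 0.0935, 9.0e-04),   # male: A, B, c
        1: (2.3e-05, 0.0955, 5.5e-04),   # female
    }
    ages = np.arange(MAX_AGE + 1, dtype=float)
    tables = {}
    for sex, (A, B, c) in base.items():
        jit = 1.0 + 0.04 * (uniform(seed, np.arange(3), 0, 100 + sex) - 0.5)
        q = c * jit[2] + A * jit[0] * np.exp(B * jit[1] * ages)
        q = np.clip(q, 0.0, 1.0)
        q[MAX_AGE] = 1.0
        tables[sex] = q
    return LifeTable(tables[0], tables[1])


# ---------------------------------------------------------------------------
# calibration targets
# ---------------------------------------------------------------------------

_TARGET_LESIONS = (
    HealthState.NonAtrophicGastritis,
    HealthState.AtrophicGastritis,
    HealthState.IntestinalMetaplasia,
    HealthState.Dysplasia,
)
_PREVALENCE_AGES = (40, 50, 60, 70)
_INCIDENCE_AGES = (40, 50, 60, 70, 80)


@dataclass
class CalibrationTargets:
    """Epidemiologic quantities the transition engine is fitted to."""

    lesion_prevalence: pd.DataFrame   # columns: age, lesion, value, tol, weight
    gc_incidence: pd.DataFrame        # columns: age, value, tol, weight
    stage_distribution: pd.DataFrame  # columns: stage, value, tol, weight

    def validate(self) -> None:
        for df, col in ((self.lesion_prevalence, "value"),
                        (self.gc_incidence, "value"),
                        (self.stage_distribution, "value")):
            v = df[col].to_numpy()
            if np.any((v < 0) | (v > 1)):
                raise ValueError("target proportions must lie in [0,1]")
        if abs(self.stage_distribution.value.sum() - 1.0) > 1e-9:
            raise ValueError("stage distribution must sum to 1")

    def to_json(self, path=None) -> str:
        payload = {
            "lesion_prevalence": self.lesion_prevalence.to_dict("records"),
            "gc_incidence": self.gc_incidence.to_dict("records"),
            "stage_distribution": self.stage_distribution.to_dict("records"),
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "CalibrationTargets":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        d = json.loads(text)
        return cls(
            pd.DataFrame(d["lesion_prevalence"]),
            pd.DataFrame(d["gc_incidence"]),
            pd.DataFrame(d["stage_distribution"]),
        )


def generate_calibration_targets(
    parameter_set: ParameterSet, seed: int = 0, noise_sd: float = 0.0,
    life_table: "LifeTable | None" = None,
) -> CalibrationTargets:
    """Targets recorded from the deterministic cohort engine run with a
    known truth parameter set: age-specific precancerous lesion prevalence,
    annual GC incidence, and the clinical stage distribution (advanced-stage
    dominated).  ``noise_sd`` adds multiplicative lognormal observation
    noise (default none, so parameter recovery is exactly testable).
    """
    from .natural_history import cohort_matrix_oracle

    lt = life_table if life_table is not None else generate_life_table(seed)
    oracle = cohort_matrix_oracle(parameter_set, lt)
    rows_prev = []
    for age in _PREVALENCE_AGES:
        for lesion in _TARGET_LESIONS:
            rows_prev.append(
                dict(age=age, lesion=lesion.name,
                     value=oracle.prevalence(age, lesion), tol=0.15, weight=1.0)
            )
    rows_inc = [
        dict(age=age, value=oracle.incidence_rate(age), tol=0.15, weight=1.0)
        for age in _INCIDENCE_AGES
    ]
    stage = oracle.stage_distribution
    rows_stage = [
        dict(stage=k + 1, value=float(stage[k]), tol=0.15, weight=1.0) for k in range(4)
    ]
    targets = CalibrationTargets(
        pd.DataFrame(rows_prev), pd.DataFrame(rows_inc), pd.DataFrame(rows_stage)
    )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        for df in (targets.lesion_prevalence, targets.gc_incidence):
            df["value"] = np.clip(
                df["value"] * rng.lognormal(0.0, noise_sd, len(df)), 0.0, 1.0
            )
    # renormalize defensively; noise never touches the stage rows
    targets.stage_distribution["value"] /= targets.stage_distribution["value"].sum()
    targets.validate()
    return targets
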