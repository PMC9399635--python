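"""Counter-based random numbers keyed by (seed, individual id, year, purpose).

Every stochastic decision in the microsimulation draws from a stateless
hash of its coordinates, so results are independent of processing order
and the same individual re-uses the same substream under every screening
strategy (common random numbers).  The mixer is the splitmix64 finalizer,
applied after folding each coordinate in with a distinct odd constant.
"""

from __future__ import annotations

import numpy as np

_U64 = np.uint64
_PHI = _U64(0x9E3779B97F4A7C15)  # golden-ratio increment
_C1 = _U64(0xBF58476D1CE4E5B9)
_C2 = _U64(0x94D049BB133111EB)

# purpose codes — one substream per kind of decision
TRANSITION = 1
SEROLOGY_HP = 2
SEROLOGY_ATROPHY = 3
ENDO_DETECT = 4
ENDO_FALSE_POS = 5
TREAT_CHOICE = 6
BLEEDING = 7
PERFORATION = 8
BLEEDING_FATAL = 9
PERFORATION_FATAL = 10
SURGERY_DEATH = 11
ERADICATION = 12
INIT_SEX = 13
INIT_HP = 14
INIT_SMOKING = 15
INIT_SMOKING_HEAVY = 16


def _mix(x: np.ndarray) -> np.ndarray:
    x = (x ^ (x >> _U64(30))) * _C1
    x = (x ^ (x >> _U64(27))) * _C2
    return x ^ (x >> _U64(31))


def hash_u64(seed: int, ids, year: int, purpose: int) -> np.ndarray:
    ids = np.asarray(ids, dtype=np.uint64)
    h = _mix(_U64(seed & 0xFFFFFFFFFFFFFFFF) * _PHI + _U64(1))
    h = _mix(h ^ (ids * _PHI + _U64(0x2545F4914F6CDD1D)))
    h = _mix(h ^ (_U64(year) * _C1 + _U64(purpose) * _C2))
    return h


def uniform(seed: int, ids, year: int, purpose: int) -> np.ndarray:
    """Vector of U(0,1) doubles, one per id, reproducible and order-free."""
    with np.errstate(over="ignore"):
        h = hash_u64(seed, ids, year, purpose)
    return (h >> _U64(11)).astype(np.float64) * (2.0 ** -53)


class CounterRng:
    """Per-individual substream view used by the scalar (one-person) API.

    Wraps (seed, id) and serves uniforms indexed by (year, purpose, draw).
    """

    def __init__(self, seed: int, individual_id: int = 0):
        self.seed = int(seed)
        self.id = int(individual_id)

    def u(self, year: int, purpose: int, draw: int = 0) -> float:
        # extra draws within the same (year, purpose) offset the purpose code
        return float(uniform(self.seed, [self.id], year, purpose + (draw << 8))[0])
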