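"""Absorbing-state cohort Markov engine.

The engine advances a cohort distributed over seven health states in annual
cycles, applying age-dependent transition matrices, accruing per-state costs
and utilities each cycle, and discounting both streams at a constant annual
rate.  It is deliberately generic: the screening-specific strategy wiring
lives in :mod:`uiascreen.strategies`, which compiles down to the
:class:`TransitionModel` / :class:`CycleValueModel` pair consumed here.

States
------
Seven states describe an individual's status with respect to an unruptured
intracranial aneurysm (UIA) and disability after aneurysmal subarachnoid
hemorrhage (SAH):

* four "healthy" states (no aneurysm; undetected carrier; detected carrier in
  imaging follow-up; screened false negative) sharing one utility weight,
* moderate and severe disability after SAH (or treatment complications),
* dead (absorbing).

Utilities derive from the modified Rankin scale (mRS) collapsed into four
classes; see :func:`mrs_to_utility`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HealthState",
    "N_STATES",
    "CollapsedClass",
    "UtilityTable",
    "LifeTable",
    "DiscountSpec",
    "TransitionModel",
    "CycleValueModel",
    "CohortTrace",
    "ModelValidationError",
    "run_cohort",
    "discounted_sum",
    "life_expectancy",
    "mrs_to_utility",
]


class ModelValidationError(ValueError):
    """Raised when an input violates a structural model invariant."""


class HealthState(enum.IntEnum):
    """The seven Markov states, in canonical matrix order."""

    HEALTHY_NO_ANEURYSM = 0
    HEALTHY_WITH_ANEURYSM = 1
    HEALTHY_ANEURYSM_FOLLOWUP = 2
    HEALTHY_FALSE_NEGATIVE = 3
    MODERATE_DISABILITY = 4
    SEVERE_DISABILITY = 5
    DEAD = 6

    @property
    def collapsed_class(self) -> "CollapsedClass":
        return _COLLAPSED[self]


CollapsedClass = Literal["healthy", "moderate", "severe", "dead"]

_COLLAPSED: dict[HealthState, CollapsedClass] = {
    HealthState.HEALTHY_NO_ANEURYSM: "healthy",
    HealthState.HEALTHY_WITH_ANEURYSM: "healthy",
    HealthState.HEALTHY_ANEURYSM_FOLLOWUP: "healthy",
    HealthState.HEALTHY_FALSE_NEGATIVE: "healthy",
    HealthState.MODERATE_DISABILITY: "moderate",
    HealthState.SEVERE_DISABILITY: "severe",
    HealthState.DEAD: "dead",
}

N_STATES = len(HealthState)

#: mRS -> collapsed utility weight (dead maps to 0).
_MRS_UTILITY = {0: 0.93, 1: 0.93, 2: 0.76, 3: 0.76, 4: 0.235, 5: 0.235, 6: 0.0}


def mrs_to_utility(mrs: int) -> float:
    """Collapsed utility weight for a modified Rankin scale grade.

    mRS 0-1 (no/insignificant symptoms) -> 0.93, 2-3 (moderate disability)
    -> 0.76, 4-5 (severe disability) -> 0.235, 6 (dead) -> 0.
    """
    if mrs not in _MRS_UTILITY:
        raise ModelValidationError(f"mRS grade must be an integer in 0..6, got {mrs!r}")
    return _MRS_UTILITY[mrs]


@dataclass(frozen=True)
class UtilityTable:
    """Annual utility weight per collapsed health class."""

    healthy: float = 0.93
    moderate: float = 0.76
    severe: float = 0.235
    dead: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.healthy, self.moderate, self.severe, self.dead)
        if not all(0.0 <= v <= 1.0 for v in vals):
            raise ModelValidationError(f"utilities must lie in [0, 1], got {vals}")
        if self.dead != 0.0:
            raise ModelValidationError("the dead state must carry utility 0")
        if not (self.healthy >= self.moderate >= self.severe):
            raise ModelValidationError(
                "utilities must be ordered healthy >= moderate >= severe, got "
                f"{self.healthy}, {self.moderate}, {self.severe}"
            )

    def as_state_vector(self) -> np.ndarray:
        by_class = {"healthy": self.healthy, "moderate": self.moderate,
                    "severe": self.severe, "dead": self.dead}
        return np.array([by_class[s.collapsed_class] for s in HealthState])


class LifeTable:
    """Age- and disability-stratified annual death probabilities.

    Rows are contiguous integer ages; columns give the annual probability of
    death for the healthy, moderately disabled, and severely disabled strata.
    Ages beyond the terminal row are treated as certain death, which
    guarantees cohort extinction.
    """

    COLUMNS = ("age", "q_healthy", "q_moderate", "q_severe")

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in frame.columns]
        if missing:
            raise ModelValidationError(f"life table is missing columns {missing}")
        frame = frame.loc[:, list(self.COLUMNS)].copy()
        frame["age"] = frame["age"].astype(int)
        frame = frame.sort_values("age").reset_index(drop=True)
        ages = frame["age"].to_numpy()
        if len(ages) == 0:
            raise ModelValidationError("life table is empty")
        if not np.all(np.diff(ages) == 1):
            raise ModelValidationError("life table ages must be contiguous integers")
        q = frame[["q_healthy", "q_moderate", "q_severe"]].to_numpy(float)
        if np.any(q < 0) or np.any(q > 1):
            raise ModelValidationError("death probabilities must lie in [0, 1]")
        if np.any(q[:, 1] < q[:, 0] - 1e-12) or np.any(q[:, 2] < q[:, 1] - 1e-12):
            raise ModelValidationError(
                "life table must satisfy q_severe >= q_moderate >= q_healthy at every age"
            )
        self._frame = frame
        self._age0 = int(ages[0])
        self._q = q

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame.copy()

    @property
    def min_age(self) -> int:
        return self._age0

    @property
    def max_age(self) -> int:
        return self._age0 + len(self._frame) - 1

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self._frame.to_csv(path, index=False)

    def q(self, age: int, cls_: CollapsedClass = "healthy") -> float:
        """Annual death probability at ``age`` for a disability stratum."""
        if cls_ == "dead":
            return 1.0
        col = {"healthy": 0, "moderate": 1, "severe": 2}[cls_]
        i = int(age) - self._age0
        if i < 0:
            raise ModelValidationError(
                f"age {age} precedes the life table's first row ({self._age0})"
            )
        if i >= len(self._q):  # beyond terminal age: certain death
            return 1.0
        return float(self._q[i, col])

    def q_vector(self, age: int) -> np.ndarray:
        """Per-state annual death probability at ``age`` (DEAD entry is 1)."""
        by_class = {c: self.q(age, c) for c in ("healthy", "moderate", "severe")}
        by_class["dead"] = 1.0
        return np.array([by_class[s.collapsed_class] for s in HealthState])


DiscountConvention = Literal["first-cycle-undiscounted", "first-cycle-discounted"]


@dataclass(frozen=True)
class DiscountSpec:
    """Constant annual discounting of costs and effects.

    With the default ``first-cycle-undiscounted`` convention, cycle ``t``
    values are divided by ``(1 + rate) ** t`` (cycle 0 at face value); the
    alternative convention uses exponent ``t + 1``.
    """

    annual_rate: float = 0.03
    convention: DiscountConvention = "first-cycle-undiscounted"

    def __post_init__(self) -> None:
        if self.annual_rate < 0:
            raise ModelValidationError(f"discount rate must be >= 0, got {self.annual_rate}")
        if self.convention not in ("first-cycle-undiscounted", "first-cycle-discounted"):
            raise ModelValidationError(f"unknown discount convention {self.convention!r}")

    def factors(self, n: int) -> np.ndarray:
        t = np.arange(n, dtype=float)
        if self.convention == "first-cycle-discounted":
            t = t + 1.0
        return (1.0 + self.annual_rate) ** (-t)


class TransitionModel:
    """Generator of age-dependent row-stochastic transition matrices.

    Wraps a callable ``(cycle, age) -> (7, 7) ndarray``.  Each produced row
    must sum to one and the DEAD row must be the unit vector on DEAD.
    """

    def __init__(self, matrix_fn: Callable[[int, int], np.ndarray]):
        self._fn = matrix_fn

    def matrix(self, cycle: int, age: int) -> np.ndarray:
        return np.asarray(self._fn(cycle, age), dtype=float)

    @staticmethod
    def validate_matrix(P: np.ndarray, cycle: int) -> None:
        if P.shape != (N_STATES, N_STATES):
            raise ModelValidationError(
                f"cycle {cycle}: transition matrix has shape {P.shape}, expected "
                f"({N_STATES}, {N_STATES})"
            )
        if np.any(P < -1e-15):
            i, j = np.argwhere(P < -1e-15)[0]
            raise ModelValidationError(
                f"cycle {cycle}: negative transition probability in row "
                f"{HealthState(i).name} -> {HealthState(j).name}"
            )
        sums = P.sum(axis=1)
        bad = np.where(np.abs(sums - 1.0) > 1e-12)[0]
        if bad.size:
            r = int(bad[0])
            raise ModelValidationError(
                f"cycle {cycle}: row {HealthState(r).name} sums to {sums[r]!r}, not 1"
            )
        dead = np.zeros(N_STATES)
        dead[HealthState.DEAD] = 1.0
        if not np.allclose(P[HealthState.DEAD], dead, atol=1e-12):
            raise ModelValidationError(f"cycle {cycle}: DEAD row is not absorbing")

    @classmethod
    def constant(cls, P: np.ndarray) -> "TransitionModel":
        P = np.asarray(P, dtype=float)
        return cls(lambda cycle, age: P)


class CycleValueModel:
    """Per-cycle value accrual attached to states and events.

    ``state_cost(cycle)`` is the euro cost charged per occupant of each state
    during that cycle (imaging schedules and annual care costs live here).
    ``event_cost(cycle)`` is the expected one-time euro cost attached to
    occupying a state at the start of a cycle whose stochastic events (rupture,
    detection, treatment) fire during it; it is charged in the following
    cycle.  ``entry_cost`` is a lump charged at cycle 0 (the screening
    cascade).
    """

    def __init__(
        self,
        utilities: UtilityTable | np.ndarray,
        state_cost: Callable[[int], np.ndarray] | np.ndarray | None = None,
        event_cost: Callable[[int], np.ndarray] | np.ndarray | None = None,
        entry_cost: float = 0.0,
    ):
        if isinstance(utilities, UtilityTable):
            self.utilities = utilities.as_state_vector()
        else:
            self.utilities = np.asarray(utilities, dtype=float)
        if self.utilities.shape != (N_STATES,):
            raise ModelValidationError("utilities must be a length-7 vector")
        self._state_cost = self._as_fn(state_cost)
        self._event_cost = self._as_fn(event_cost)
        if entry_cost < 0:
            raise ModelValidationError("entry cost must be >= 0")
        self.entry_cost = float(entry_cost)

    @staticmethod
    def _as_fn(spec):
        if spec is None:
            zero = np.zeros(N_STATES)
            return lambda cycle: zero
        if callable(spec):
            return spec
        arr = np.asarray(spec, dtype=float)
        if arr.shape != (N_STATES,):
            raise ModelValidationError("cost vectors must have length 7")
        if np.any(arr < 0):
            raise ModelValidationError("costs must be >= 0")
        return lambda cycle: arr

    def state_cost(self, cycle: int) -> np.ndarray:
        return np.asarray(self._state_cost(cycle), dtype=float)

    def event_cost(self, cycle: int) -> np.ndarray:
        return np.asarray(self._event_cost(cycle), dtype=float)


AccrualConvention = Literal["cycle-start", "cycle-end", "half-cycle"]


@dataclass
class CohortTrace:
    """Per-cycle occupancy and value ledger of a cohort run.

    ``occupancy[t]`` is the cohort distribution at the *start* of cycle ``t``.
    ``cycle_cost`` / ``cycle_qaly`` are raw per-cycle totals under the stated
    accrual convention; ``disc_cost`` / ``disc_qaly`` are their discounted
    counterparts.
    """

    occupancy: np.ndarray
    cycle_cost: np.ndarray
    cycle_qaly: np.ndarray
    disc_cost: np.ndarray
    disc_qaly: np.ndarray
    entry_age: int
    accrual: AccrualConvention = "cycle-start"

    def __post_init__(self) -> None:
        sums = self.occupancy.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            t = int(np.argmax(np.abs(sums - 1.0) > 1e-9))
            raise ModelValidationError(
                f"occupancy row {t} sums to {sums[t]!r}, not 1 (tolerance 1e-9)"
            )
        dead = self.occupancy[:, HealthState.DEAD]
        if np.any(np.diff(dead) < -1e-12):
            raise ModelValidationError("DEAD occupancy must be non-decreasing")

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0]

    @property
    def alive(self) -> np.ndarray:
        return 1.0 - self.occupancy[:, HealthState.DEAD]

    @property
    def total_cost(self) -> float:
        return float(self.cycle_cost.sum())

    @property
    def total_qaly(self) -> float:
        return float(self.cycle_qaly.sum())

    @property
    def total_disc_cost(self) -> float:
        return float(self.disc_cost.sum())

    @property
    def total_disc_qaly(self) -> float:
        return float(self.disc_qaly.sum())

    def accrual_weights(self, series: np.ndarray) -> np.ndarray:
        """Weight a per-cycle-start series by the trace's accrual convention.

        A trace with ``n`` occupancy rows represents ``n - 1`` lived cycles;
        cycle-start accrual uses the occupancy opening each lived cycle,
        cycle-end the occupancy closing it, half-cycle their average.
        """
        s = np.asarray(series, dtype=float)
        out = np.zeros_like(s)
        if len(s) < 2:
            return out
        if self.accrual == "cycle-start":
            out[:-1] = s[:-1]
        elif self.accrual == "cycle-end":
            out[1:] = s[1:]
        else:  # half-cycle
            out[:-1] = 0.5 * (s[:-1] + s[1:])
        return out

    def to_frame(self) -> pd.DataFrame:
        cols = {"cycle": np.arange(self.n_cycles),
                "age": self.entry_age + np.arange(self.n_cycles)}
        for s in HealthState:
            cols[s.name.lower()] = self.occupancy[:, s]
        cols["cycle_cost"] = self.cycle_cost
        cols["cycle_qaly"] = self.cycle_qaly
        cols["disc_cost"] = self.disc_cost
        cols["disc_qaly"] = self.disc_qaly
        return pd.DataFrame(cols)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def run_cohort(
    initial: Sequence[float] | np.ndarray,
    transitions: TransitionModel,
    values: CycleValueModel,
    discount: DiscountSpec,
    max_cycles: int = 100,
    *,
    entry_age: int = 40,
    accrual: AccrualConvention = "cycle-start",
    extinction_tol: float = 1e-9,
) -> CohortTrace:
    """Advance a cohort to extinction (or ``max_cycles``) and tally values.

    The cohort starts with distribution ``initial`` at ``entry_age``.  Each
    cycle applies the transition matrix for that cycle/age, accrues per-state
    costs and utilities under the ``accrual`` convention, charges expected
    event costs one cycle after the occupancy that generates them, and
    discounts everything per ``discount``.  The run stops at the first cycle
    where the non-DEAD occupancy falls below ``extinction_tol``.
    """
    init = np.asarray(initial, dtype=float)
    if init.shape != (N_STATES,):
        raise ModelValidationError(f"initial distribution must have length {N_STATES}")
    if np.any(init < 0) or abs(init.sum() - 1.0) > 1e-9:
        raise ModelValidationError(
            f"initial distribution must be non-negative and sum to 1, got sum {init.sum()!r}"
        )
    if max_cycles < 1:
        raise ModelValidationError("max_cycles must be >= 1")

    occ_rows = [init]
    event_charges = [0.0]  # charged at cycle t+1 from occupancy at t
    occ = init
    for t in range(max_cycles):
        alive = 1.0 - occ[HealthState.DEAD]
        if alive < extinction_tol:
            break
        P = transitions.matrix(t, entry_age + t)
        TransitionModel.validate_matrix(P, t)
        event_charges.append(float(occ @ values.event_cost(t)))
        occ = occ @ P
        occ = np.maximum(occ, 0.0)
        occ = occ / occ.sum()
        occ_rows.append(occ)

    occupancy = np.vstack(occ_rows)
    n = occupancy.shape[0]

    state_costs = np.array([occupancy[t] @ values.state_cost(t) for t in range(n)])
    qalys = occupancy @ values.utilities

    trace = CohortTrace(
        occupancy=occupancy,
        cycle_cost=np.zeros(n),
        cycle_qaly=np.zeros(n),
        disc_cost=np.zeros(n),
        disc_qaly=np.zeros(n),
        entry_age=entry_age,
        accrual=accrual,
    )
    cost = trace.accrual_weights(state_costs)
    qaly = trace.accrual_weights(qalys)
    cost = cost + np.asarray(event_charges[:n])
    cost[0] += values.entry_cost

    f = discount.factors(n)
    trace.cycle_cost = cost
    trace.cycle_qaly = qaly
    trace.disc_cost = cost * f
    trace.disc_qaly = qaly * f
    return trace


def discounted_sum(series: Iterable[float], discount: DiscountSpec) -> float:
    """Discounted sum of a per-cycle value series under ``discount``."""
    s = np.asarray(list(series), dtype=float)
    if not np.all(np.isfinite(s)):
        raise ModelValidationError("series must be finite")
    return float(s @ discount.factors(len(s)))


def life_expectancy(trace: CohortTrace) -> float:
    """Undiscounted expected years alive, using the trace's accrual convention."""
    return float(trace.accrual_weights(trace.alive).sum())
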