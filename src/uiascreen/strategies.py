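"""Strategy assembly: screening cascade, follow-up schedules, SAH sub-tree.

This module turns a parameter set into the two comparator arms of the
decision model:

* **SOC** (standard of care): nobody is screened; aneurysm carriers are
  undetected until incidental imaging finds them, after which they enter the
  same watchful-waiting / prophylactic-treatment logic as screen-detected
  carriers.
* **PWS** (population-wide screening): a single screen at cohort entry sorts
  the population through a test cascade (true/false positives and negatives),
  with confirmatory MRA for positives, DSA for treatment-bound positives, and
  immediate prophylactic treatment of the treat-indicated fraction.

Both arms share life-table mortality, rupture dynamics, the SAH outcome
sub-tree, and follow-up imaging schedules.  ``assemble_strategy`` compiles an
arm into the generic :class:`~uiascreen.markov.TransitionModel` /
:class:`~uiascreen.markov.CycleValueModel` pair plus an initial distribution.

Follow-up imaging is charged as an expected present value at the moment a
person enters a followed or treated status: each scheduled exam is weighted
by the probability of still being alive (and, for watchful waiting, still
unruptured and unescalated) when it is due, and discounted back to the event.
"""

from __future__ import annotations

import math
from typing import Literal

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .markov import (
    CycleValueModel,
    HealthState,
    LifeTable,
    ModelValidationError,
    N_STATES,
    TransitionModel,
    UtilityTable,
)

__all__ = [
    "ScreeningTest",
    "ImagingCosts",
    "EpidemiologyParams",
    "SahOutcomeModel",
    "TreatmentParams",
    "FollowUpSchedule",
    "DEFAULT_SCHEDULES",
    "annualize_risk",
    "screening_cascade",
    "followup_cost_stream",
    "sah_event_subtree",
    "assemble_strategy",
]

_S = HealthState

Proportion = Field(ge=0.0, le=1.0)
Euro = Field(ge=0.0)


class _Params(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class ScreeningTest(_Params):
    """A screening instrument: diagnostic accuracy, price, and scope.

    ``risk_stratifying`` marks a test whose positive result directly implies
    treatment need, so no confirmatory MRA is charged (scenario 2).
    ``reusable_in_followup`` lets the same test replace imaging in the
    watchful-waiting schedule of low-risk carriers.  ``cost_recurring``
    selects the cost wiring: when true the unit cost is charged annually to
    every living member of the screened arm; when false it is charged once at
    the screen.
    """

    sensitivity: float = Proportion
    specificity: float = Proportion
    unit_cost: float = Euro
    risk_stratifying: bool = False
    reusable_in_followup: bool = False
    cost_recurring: bool = True


class ImagingCosts(_Params):
    """Unit costs of the three angiographic modalities (euro per exam)."""

    mra_cost: float = Field(811.30, ge=0)
    cta_cost: float = Field(661.30, ge=0)
    dsa_cost: float = Field(1800.0, ge=0)


class EpidemiologyParams(_Params):
    """Prevalence, rupture, formation, and detection dynamics.

    Rupture risks are annual probabilities.  ``fraction_treat_indicated`` is
    the share of detected carriers whose rupture risk indicates prophylactic
    treatment; the rest enter watchful waiting.
    ``annual_escalation_prob`` is the annual probability that a carrier under
    watchful waiting is escalated to treatment (growth or risk reassessment
    on surveillance imaging).  ``sah_before_entry_fraction`` is the share of
    preventable ruptures that occur before the entry age and therefore cannot
    be averted by a single screen at entry.
    """

    uia_prevalence_at_entry: float = Proportion
    annual_rupture_risk_conservative: float = Proportion
    annual_rupture_risk_treat_indicated: float = Proportion
    fraction_treat_indicated: float = Proportion
    de_novo_annual_incidence: float = Proportion
    incidental_detection_annual_prob: float = Proportion
    annual_escalation_prob: float = Field(0.0, ge=0.0, le=1.0)
    sah_before_entry_fraction: float = Field(0.10, ge=0.0, le=1.0)


class SahOutcomeModel(_Params):
    """One-year outcome distribution and cost bundle of an SAH event.

    The landing distribution over collapsed classes is conditional on
    rupture; ``p_favorable`` is the healthy share.  The acute cost covers
    aneurysm repair, intensive care, and in-hospital imaging; rehabilitation
    is class-specific; disabled survivors additionally accrue annual care
    costs through the state-cost channel.
    """

    p_favorable: float = Field(0.545, ge=0.0, le=1.0)
    p_moderate: float = Proportion
    p_severe: float = Proportion
    p_dead: float = Proportion
    acute_treatment_cost: float = Euro
    rehab_cost_healthy: float = Euro
    rehab_cost_moderate: float = Euro
    rehab_cost_severe: float = Euro
    annual_care_cost_moderate: float = Euro
    annual_care_cost_severe: float = Euro

    @model_validator(mode="after")
    def _check_distribution(self) -> "SahOutcomeModel":
        total = self.p_favorable + self.p_moderate + self.p_severe + self.p_dead
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"SAH outcome distribution must sum to 1, got {total!r} "
                "(p_favorable + p_moderate + p_severe + p_dead)"
            )
        return self


class TreatmentParams(_Params):
    """Prophylactic occlusion: modality mix, costs, procedural risks."""

    p_clip: float = Field(0.444, ge=0.0, le=1.0)
    p_endo: float = Field(0.556, ge=0.0, le=1.0)
    clip_cost: float = Euro
    endo_cost: float = Euro
    p_death_clip: float = Proportion
    p_morbidity_clip: float = Proportion
    p_death_endo: float = Proportion
    p_morbidity_endo: float = Proportion

    @model_validator(mode="after")
    def _check_mix(self) -> "TreatmentParams":
        if abs(self.p_clip + self.p_endo - 1.0) > 1e-9:
            raise ValueError(f"p_clip + p_endo must equal 1, got {self.p_clip + self.p_endo!r}")
        return self

    @property
    def p_death(self) -> float:
        return self.p_clip * self.p_death_clip + self.p_endo * self.p_death_endo

    @property
    def p_morbidity(self) -> float:
        return self.p_clip * self.p_morbidity_clip + self.p_endo * self.p_morbidity_endo

    @property
    def procedure_cost(self) -> float:
        return self.p_clip * self.clip_cost + self.p_endo * self.endo_cost


Modality = Literal["MRA", "CTA", "TEST"]
ScheduleContext = Literal["untreated_uia", "post_clip", "post_coil"]


class FollowUpSchedule(_Params):
    """An imaging schedule: a finite prefix plus an optional periodic tail.

    Offsets are years from the index event and may be sub-annual; they are
    binned into annual model cycles by :func:`followup_cost_stream`.
    """

    context: ScheduleContext
    prefix: list[tuple[float, Modality]] = []
    tail_start: float | None = None
    tail_interval: float | None = None
    tail_modality: Modality | None = None

    @model_validator(mode="after")
    def _check_offsets(self) -> "FollowUpSchedule":
        offs = [o for o, _ in self.prefix]
        if any(o < 0 for o in offs):
            raise ValueError("schedule offsets must be non-negative")
        if any(b < a for a, b in zip(offs, offs[1:])):
            raise ValueError("schedule prefix offsets must be non-decreasing")
        if (self.tail_start is None) != (self.tail_interval is None):
            raise ValueError("tail_start and tail_interval must be given together")
        if self.tail_interval is not None and self.tail_interval <= 0:
            raise ValueError("tail_interval must be positive")
        return self


#: Institutional surveillance algorithms: annual MRA for five years then
#: biennial for untreated carriers; CTA every five years after clipping; MRA
#: at discharge, 6, 18, and 36 months after coiling, then every three years.
DEFAULT_SCHEDULES: dict[ScheduleContext, FollowUpSchedule] = {
    "untreated_uia": FollowUpSchedule(
        context="untreated_uia",
        prefix=[(float(y), "MRA") for y in range(1, 6)],
        tail_start=7.0, tail_interval=2.0, tail_modality="MRA",
    ),
    "post_clip": FollowUpSchedule(
        context="post_clip",
        tail_start=5.0, tail_interval=5.0, tail_modality="CTA",
    ),
    "post_coil": FollowUpSchedule(
        context="post_coil",
        prefix=[(0.0, "MRA"), (0.5, "MRA"), (1.5, "MRA"), (3.0, "MRA")],
        tail_start=6.0, tail_interval=3.0, tail_modality="MRA",
    ),
}


def annualize_risk(cumulative_risk: float, horizon: float) -> float:
    """Convert a cumulative risk over ``horizon`` years to a mean annual one.

    Inverts constant-hazard compounding: ``1 - (1 - c) ** (1 / horizon)``.
    """
    if not 0.0 <= cumulative_risk < 1.0:
        raise ModelValidationError(
            f"cumulative risk must lie in [0, 1), got {cumulative_risk!r}"
        )
    if horizon <= 0:
        raise ModelValidationError(f"horizon must be positive, got {horizon!r}")
    return 1.0 - (1.0 - cumulative_risk) ** (1.0 / horizon)


def _bin_offset(offset: float) -> int:
    """Assign a years-from-index offset to an annual cycle.

    Integer offsets map to their own year.  Half-year offsets resolve to the
    nearest odd year, so the 6- and 18-month post-coil scans share the year-1
    surveillance cycle.
    """
    base = math.floor(offset)
    frac = offset - base
    if frac < 0.5 - 1e-12:
        return base
    if frac > 0.5 + 1e-12:
        return base + 1
    return base if base % 2 == 1 else base + 1


def _modality_cost(modality: str, imaging: ImagingCosts, test: ScreeningTest | None) -> float:
    if modality == "MRA":
        return imaging.mra_cost
    if modality == "CTA":
        return imaging.cta_cost
    if modality == "TEST":
        if test is None:
            raise ModelValidationError("schedule uses TEST modality but no test was given")
        return test.unit_cost
    raise ModelValidationError(f"unknown imaging modality {modality!r}")


def followup_cost_stream(
    schedule: FollowUpSchedule,
    imaging: ImagingCosts,
    test: ScreeningTest | None = None,
    horizon: int = 60,
) -> np.ndarray:
    """Per-cycle euro cost vector of a follow-up schedule over ``horizon`` years.

    When the test is reusable in follow-up, TEST replaces MRA in the
    untreated-carrier stream at the test's unit cost (and costs nothing extra
    under the recurring wiring, where the test is already charged annually).
    """
    stream = np.zeros(horizon + 1)
    entries: list[tuple[float, str]] = list(schedule.prefix)
    if schedule.tail_start is not None:
        k = 0
        while True:
            off = schedule.tail_start + k * schedule.tail_interval
            if off > horizon:
                break
            entries.append((off, schedule.tail_modality))
            k += 1
    reusable = (
        test is not None
        and test.reusable_in_followup
        and schedule.context == "untreated_uia"
    )
    for off, modality in entries:
        if reusable and modality == "MRA":
            modality = "TEST"
            cost = 0.0 if test.cost_recurring else test.unit_cost
        else:
            cost = _modality_cost(modality, imaging, test)
        b = _bin_offset(off)
        if b <= horizon:
            stream[b] += cost
    return stream


def sah_event_subtree(outcome: SahOutcomeModel) -> tuple[np.ndarray, float]:
    """Landing distribution over states and expected immediate cost of an SAH.

    Favorable outcomes return to the aneurysm-free healthy state (the
    ruptured aneurysm is secured during the acute admission); the rest land
    in moderate disability, severe disability, or death.  The cost is the
    acute bundle plus class-weighted rehabilitation; ongoing care costs of
    disabled survivors accrue per cycle through the value model.
    """
    landing = np.zeros(N_STATES)
    landing[_S.HEALTHY_NO_ANEURYSM] = outcome.p_favorable
    landing[_S.MODERATE_DISABILITY] = outcome.p_moderate
    landing[_S.SEVERE_DISABILITY] = outcome.p_severe
    landing[_S.DEAD] = outcome.p_dead
    if abs(landing.sum() - 1.0) > 1e-9:
        raise ModelValidationError("SAH landing distribution must sum to 1")
    cost = outcome.acute_treatment_cost + (
        outcome.p_favorable * outcome.rehab_cost_healthy
        + outcome.p_moderate * outcome.rehab_cost_moderate
        + outcome.p_severe * outcome.rehab_cost_severe
    )
    return landing, float(cost)


class _StreamPV:
    """Present value of follow-up streams at each possible event cycle.

    Each scheduled exam is weighted by the probability that the person is
    still in the followed status when it is due (alive for treated contexts;
    alive, unruptured, and unescalated for watchful waiting) and discounted
    to the event cycle.
    """

    def __init__(
        self,
        lifetable: LifeTable,
        entry_age: int,
        max_cycles: int,
        rate: float,
        horizon: int = 60,
    ):
        self.horizon = horizon
        self.disc = (1.0 + rate) ** -np.arange(horizon + 1)
        # healthy-stratum survival q over ages entry..entry+max_cycles+horizon
        ages = np.arange(entry_age, entry_age + max_cycles + horizon + 2)
        self.q_h = np.array([lifetable.q(a, "healthy") for a in ages])
        self.max_cycles = max_cycles

    def pv(self, stream: np.ndarray, event_cycle: int, exit_prob: float = 0.0) -> float:
        t0 = min(event_cycle, self.max_cycles)
        q = self.q_h[t0 : t0 + self.horizon + 1]
        retain = np.ones(self.horizon + 1)
        surv = np.cumprod((1.0 - q[: self.horizon]) * (1.0 - exit_prob))
        retain[1:] = surv
        return float(np.sum(stream * retain * self.disc))


def screening_cascade(
    test: ScreeningTest,
    epi: EpidemiologyParams,
    imaging: ImagingCosts,
    treat: TreatmentParams,
    *,
    treatment_event_cost: float | None = None,
    followup_entry_cost: float | None = None,
) -> tuple[np.ndarray, float, list[dict]]:
    """One-off screen of the whole cohort at entry.

    Returns the post-screen initial state distribution, the expected up-front
    cost per cohort member, and the branch table.  A fraction
    ``sah_before_entry_fraction`` of prevalent carriers bypasses the screen
    (ruptures that would have occurred before entry cannot be averted) and
    starts undetected, exactly as in the SOC arm.

    The optional event-cost arguments price the treatment sub-tree and the
    watchful-waiting follow-up stream at entry; they default to the bare
    procedure cost and zero so the cascade can be inspected standalone.
    """
    p = epi.uia_prevalence_at_entry
    f_ti = epi.fraction_treat_indicated
    bypass = p * epi.sah_before_entry_fraction
    screened_carriers = p - bypass

    tp = screened_carriers * test.sensitivity
    fn = screened_carriers * (1.0 - test.sensitivity)
    fp = (1.0 - p) * (1.0 - test.specificity)
    tn = (1.0 - p) * test.specificity

    if treatment_event_cost is None:
        treatment_event_cost = imaging.dsa_cost + treat.procedure_cost
    if followup_entry_cost is None:
        followup_entry_cost = 0.0

    # Per-positive confirmatory imaging: MRA unless the test itself
    # stratifies risk, in which case only treatment-bound positives reach
    # angiography (DSA is part of the treatment event cost).
    conf_mra = 0.0 if test.risk_stratifying else imaging.mra_cost
    fp_workup = imaging.dsa_cost * f_ti if test.risk_stratifying else imaging.mra_cost

    initial = np.zeros(N_STATES)
    initial[_S.HEALTHY_NO_ANEURYSM] = tn + fp
    initial[_S.HEALTHY_WITH_ANEURYSM] = bypass
    initial[_S.HEALTHY_FALSE_NEGATIVE] = fn
    treated = tp * f_ti
    initial[_S.HEALTHY_NO_ANEURYSM] += treated * (1.0 - treat.p_death - treat.p_morbidity)
    initial[_S.MODERATE_DISABILITY] = treated * treat.p_morbidity
    initial[_S.DEAD] = treated * treat.p_death
    initial[_S.HEALTHY_ANEURYSM_FOLLOWUP] = tp * (1.0 - f_ti)

    screen_charge = 0.0 if test.cost_recurring else test.unit_cost
    cost = (
        screen_charge
        + tp * conf_mra
        + fp * fp_workup
        + treated * treatment_event_cost
        + tp * (1.0 - f_ti) * followup_entry_cost
    )

    branches = [
        {"branch": "TP", "probability": tp,
         "cost": conf_mra + f_ti * treatment_event_cost + (1 - f_ti) * followup_entry_cost},
        {"branch": "FP", "probability": fp, "cost": fp_workup},
        {"branch": "FN", "probability": fn, "cost": 0.0},
        {"branch": "TN", "probability": tn, "cost": 0.0},
        {"branch": "BYPASS", "probability": bypass, "cost": 0.0},
    ]
    total = sum(b["probability"] for b in branches)
    if abs(total - 1.0) > 1e-9:
        raise ModelValidationError(f"cascade branch probabilities sum to {total!r}, not 1")
    return initial, float(cost), branches


def assemble_strategy(
    arm: Literal["SOC", "PWS"],
    params,
    lifetable: LifeTable,
) -> tuple[TransitionModel, CycleValueModel, np.ndarray]:
    """Compile an arm of the decision model for the cohort engine.

    ``params`` is a :class:`uiascreen.config.ModelParams`.  Both arms share
    transition dynamics; they differ in the initial distribution (post-screen
    versus untested), the up-front cascade cost, and — under the recurring
    wiring — an annual test charge on every living member of the PWS arm.
    """
    arm = arm.upper()
    if arm not in ("SOC", "PWS"):
        raise ModelValidationError(f"arm must be 'SOC' or 'PWS', got {arm!r}")

    epi: EpidemiologyParams = params.epidemiology
    test: ScreeningTest = params.test
    imaging: ImagingCosts = params.imaging
    treat: TreatmentParams = params.treatment
    sah: SahOutcomeModel = params.sah_outcomes
    eng = params.engine
    schedules = params.followup_schedules()

    entry_age = eng.entry_age
    max_cycles = eng.max_cycles
    rate = eng.discount_rate
    horizon = params.schedules.horizon_years

    pv = _StreamPV(lifetable, entry_age, max_cycles, rate, horizon)
    in_pws = arm == "PWS"
    stream_test = test if in_pws else None

    untreated_stream = followup_cost_stream(schedules["untreated_uia"], imaging, stream_test, horizon)
    clip_stream = followup_cost_stream(schedules["post_clip"], imaging, stream_test, horizon)
    coil_stream = followup_cost_stream(schedules["post_coil"], imaging, stream_test, horizon)

    landing, sah_immediate = sah_event_subtree(sah)
    p_alive_landing = 1.0 - sah.p_dead

    f_ti = epi.fraction_treat_indicated
    r_cons = epi.annual_rupture_risk_conservative
    r_ti = epi.annual_rupture_risk_treat_indicated
    r_undetected = f_ti * r_ti + (1.0 - f_ti) * r_cons
    d = epi.incidental_detection_annual_prob
    g = epi.annual_escalation_prob
    nu = epi.de_novo_annual_incidence

    # Exit hazard from watchful waiting, used to weight its imaging stream.
    fu_exit = r_cons + g

    def treatment_cost_at(t: int) -> float:
        post_stream = treat.p_clip * pv.pv(clip_stream, t) + treat.p_endo * pv.pv(coil_stream, t)
        survive = 1.0 - treat.p_death
        return imaging.dsa_cost + treat.procedure_cost + survive * post_stream

    def sah_cost_at(t: int) -> float:
        post_stream = treat.p_clip * pv.pv(clip_stream, t) + treat.p_endo * pv.pv(coil_stream, t)
        return sah_immediate + p_alive_landing * post_stream

    def fu_entry_cost_at(t: int) -> float:
        return pv.pv(untreated_stream, t, exit_prob=fu_exit)

    treat_vec = np.zeros(N_STATES)
    treat_vec[_S.HEALTHY_NO_ANEURYSM] = 1.0 - treat.p_death - treat.p_morbidity
    treat_vec[_S.MODERATE_DISABILITY] = treat.p_morbidity
    treat_vec[_S.DEAD] = treat.p_death

    e = {s: np.eye(N_STATES)[s] for s in _S}

    n_cached = max_cycles + 1
    P_cache = np.zeros((n_cached, N_STATES, N_STATES))
    state_cost_cache = np.zeros((n_cached, N_STATES))
    event_cost_cache = np.zeros((n_cached, N_STATES))

    care = np.zeros(N_STATES)
    care[_S.MODERATE_DISABILITY] = sah.annual_care_cost_moderate
    care[_S.SEVERE_DISABILITY] = sah.annual_care_cost_severe

    recurring = np.zeros(N_STATES)
    if in_pws and test.cost_recurring:
        for s in _S:
            if s != _S.DEAD:
                recurring[s] = test.unit_cost

    for t in range(n_cached):
        age = entry_age + t
        q_h = lifetable.q(age, "healthy")
        q_m = lifetable.q(age, "moderate")
        q_s = lifetable.q(age, "severe")
        c_tx = treatment_cost_at(t)
        c_sah = sah_cost_at(t)
        c_fu = fu_entry_cost_at(t)

        P = np.zeros((N_STATES, N_STATES))
        P[_S.DEAD, _S.DEAD] = 1.0

        # Healthy, aneurysm-free: de novo formation moves to undetected carrier.
        row = (1.0 - nu) * e[_S.HEALTHY_NO_ANEURYSM] + nu * e[_S.HEALTHY_WITH_ANEURYSM]
        P[_S.HEALTHY_NO_ANEURYSM] = (1.0 - q_h) * row
        P[_S.HEALTHY_NO_ANEURYSM, _S.DEAD] += q_h

        # Undetected carrier (and false negative): rupture, else incidental
        # detection into treatment or follow-up, else stay.
        detected = f_ti * treat_vec + (1.0 - f_ti) * e[_S.HEALTHY_ANEURYSM_FOLLOWUP]
        stay_u = d * detected + (1.0 - d) * e[_S.HEALTHY_WITH_ANEURYSM]
        row_u = r_undetected * landing + (1.0 - r_undetected) * stay_u
        P[_S.HEALTHY_WITH_ANEURYSM] = (1.0 - q_h) * row_u
        P[_S.HEALTHY_WITH_ANEURYSM, _S.DEAD] += q_h

        stay_fn = d * detected + (1.0 - d) * e[_S.HEALTHY_FALSE_NEGATIVE]
        row_fn = r_undetected * landing + (1.0 - r_undetected) * stay_fn
        P[_S.HEALTHY_FALSE_NEGATIVE] = (1.0 - q_h) * row_fn
        P[_S.HEALTHY_FALSE_NEGATIVE, _S.DEAD] += q_h

        # Watchful waiting: rupture, escalation to treatment, else stay.
        stay_fu = g * treat_vec + (1.0 - g) * e[_S.HEALTHY_ANEURYSM_FOLLOWUP]
        row_fu = r_cons * landing + (1.0 - r_cons) * stay_fu
        P[_S.HEALTHY_ANEURYSM_FOLLOWUP] = (1.0 - q_h) * row_fu
        P[_S.HEALTHY_ANEURYSM_FOLLOWUP, _S.DEAD] += q_h

        P[_S.MODERATE_DISABILITY, _S.MODERATE_DISABILITY] = 1.0 - q_m
        P[_S.MODERATE_DISABILITY, _S.DEAD] = q_m
        P[_S.SEVERE_DISABILITY, _S.SEVERE_DISABILITY] = 1.0 - q_s
        P[_S.SEVERE_DISABILITY, _S.DEAD] = q_s

        P_cache[t] = P
        state_cost_cache[t] = care + recurring

        ev = np.zeros(N_STATES)
        undetected_ev = (1.0 - q_h) * (
            r_undetected * c_sah
            + (1.0 - r_undetected) * d * (f_ti * c_tx + (1.0 - f_ti) * c_fu)
        )
        ev[_S.HEALTHY_WITH_ANEURYSM] = undetected_ev
        ev[_S.HEALTHY_FALSE_NEGATIVE] = undetected_ev
        ev[_S.HEALTHY_ANEURYSM_FOLLOWUP] = (1.0 - q_h) * (
            r_cons * c_sah + (1.0 - r_cons) * g * c_tx
        )
        event_cost_cache[t] = ev

    def matrix_fn(cycle: int, age: int) -> np.ndarray:
        return P_cache[min(cycle, n_cached - 1)]

    utilities = UtilityTable(**params.utilities.model_dump())

    if in_pws:
        initial, entry_cost, _ = screening_cascade(
            test, epi, imaging, treat,
            treatment_event_cost=treatment_cost_at(0),
            followup_entry_cost=fu_entry_cost_at(0),
        )
    else:
        p = epi.uia_prevalence_at_entry
        initial = np.zeros(N_STATES)
        initial[_S.HEALTHY_NO_ANEURYSM] = 1.0 - p
        initial[_S.HEALTHY_WITH_ANEURYSM] = p
        entry_cost = 0.0

    values = CycleValueModel(
        utilities=utilities,
        state_cost=lambda t: state_cost_cache[min(t, n_cached - 1)],
        event_cost=lambda t: event_cost_cache[min(t, n_cached - 1)],
        entry_cost=entry_cost,
    )
    return TransitionModel(matrix_fn), values, initial
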