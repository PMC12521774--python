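"""Cost-effectiveness analysis layer.

Evaluates the two strategy arms, computes incremental cost-effectiveness
ratios (ICERs) with dominance handling, solves for the screening-test price
at which screening meets a willingness-to-pay (WTP) level, sweeps prevalence,
and runs the probabilistic sensitivity analysis (PSA).

Because every cost parameter enters the cohort model linearly and costs do
not feed back into transitions, the incremental cost — and hence the ICER —
is an affine function of the test price.  The threshold solver exploits this:
two model evaluations pin the line, one more confirms the solution; a
bisection fallback engages if the affinity check fails.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd

from .config import DistributionSpec, ModelParams
from .markov import CohortTrace, LifeTable, ModelValidationError, run_cohort
from .strategies import assemble_strategy

__all__ = [
    "CEOutcome",
    "ICERResult",
    "ThresholdResult",
    "ParameterDistribution",
    "PSAResult",
    "evaluate_strategy",
    "compute_icer",
    "evaluate_icer",
    "threshold_price",
    "predict_threshold_price",
    "one_way",
    "prevalence_sweep",
    "run_psa",
    "ceac",
]

ParameterDistribution = DistributionSpec


@dataclass(frozen=True)
class CEOutcome:
    """Mean discounted cost and QALYs of one strategy arm."""

    strategy: str
    cost: float
    qalys: float

    def __post_init__(self):
        if self.cost < 0 or self.qalys < 0:
            raise ModelValidationError("cost and QALYs must be non-negative")


ICERStatus = Literal["ratio", "dominant", "dominated", "equal-effect"]


@dataclass(frozen=True)
class ICERResult:
    """Incremental cost per QALY of a comparator versus a reference arm.

    ``status`` is ``dominant`` when the comparator is cheaper and more
    effective, ``dominated`` when costlier and less effective, and
    ``equal-effect`` when the QALY increment is zero.
    """

    delta_cost: float
    delta_effect: float
    status: ICERStatus
    icer: float | None

    def as_dict(self) -> dict:
        return {"delta_cost": self.delta_cost, "delta_effect": self.delta_effect,
                "status": self.status, "icer": self.icer}


@dataclass(frozen=True)
class ThresholdResult:
    """Test price at which the screening ICER equals a WTP level."""

    wtp: float
    threshold_price: float
    attainable: bool
    evaluations: tuple[tuple[float, float], ...]  # (price, icer) pairs


@dataclass
class PSAResult:
    """Monte Carlo parameter-uncertainty analysis output.

    The summary ICER is the ratio of mean increments (ICER of means), not
    the mean of per-iteration ICERs; both ingredients are retained in the
    sample arrays.
    """

    seed: int
    n_iterations: int
    soc_cost: np.ndarray
    soc_qalys: np.ndarray
    pws_cost: np.ndarray
    pws_qalys: np.ndarray
    summary_kind: str = "ICER of mean increments (ratio of means)"

    @property
    def soc_mean(self) -> tuple[float, float]:
        return float(self.soc_cost.mean()), float(self.soc_qalys.mean())

    @property
    def pws_mean(self) -> tuple[float, float]:
        return float(self.pws_cost.mean()), float(self.pws_qalys.mean())

    @property
    def icer_of_means(self) -> float:
        d_e = self.pws_qalys.mean() - self.soc_qalys.mean()
        d_c = self.pws_cost.mean() - self.soc_cost.mean()
        return float(d_c / d_e)

    def to_frame(self) -> pd.DataFrame:
        n = self.n_iterations
        return pd.DataFrame({
            "iteration": np.tile(np.arange(n), 2),
            "arm": np.repeat(["SOC", "PWS"], n),
            "cost": np.concatenate([self.soc_cost, self.pws_cost]),
            "effect": np.concatenate([self.soc_qalys, self.pws_qalys]),
        })

    def summary(self) -> dict:
        (sc, sq), (pc, pq) = self.soc_mean, self.pws_mean
        return {
            "seed": self.seed, "n_iterations": self.n_iterations,
            "soc": {"cost": sc, "qalys": sq}, "pws": {"cost": pc, "qalys": pq},
            "icer_of_means": self.icer_of_means, "summary_kind": self.summary_kind,
        }


# ---------------------------------------------------------------------------
# Arm evaluation
# ---------------------------------------------------------------------------

def run_strategy_trace(arm: str, params: ModelParams, lifetable: LifeTable) -> CohortTrace:
    transitions, values, initial = assemble_strategy(arm, params, lifetable)
    eng = params.engine
    return run_cohort(
        initial, transitions, values, eng.discount(), eng.max_cycles,
        entry_age=eng.entry_age, accrual=eng.accrual,
    )


def evaluate_strategy(arm: str, params: ModelParams, lifetable: LifeTable) -> CEOutcome:
    """Discounted mean cost and QALYs per cohort member for one arm."""
    trace = run_strategy_trace(arm, params, lifetable)
    return CEOutcome(strategy=arm.upper(), cost=trace.total_disc_cost,
                     qalys=trace.total_disc_qaly)


def compute_icer(reference: CEOutcome, comparator: CEOutcome) -> ICERResult:
    """ICER of ``comparator`` versus ``reference`` with dominance statuses."""
    d_c = comparator.cost - reference.cost
    d_e = comparator.qalys - reference.qalys
    if d_e == 0.0:
        return ICERResult(d_c, d_e, "equal-effect", None)
    if d_e > 0 and d_c < 0:
        return ICERResult(d_c, d_e, "dominant", d_c / d_e)
    if d_e < 0 and d_c > 0:
        return ICERResult(d_c, d_e, "dominated", d_c / d_e)
    return ICERResult(d_c, d_e, "ratio", d_c / d_e)


def evaluate_icer(params: ModelParams, lifetable: LifeTable) -> tuple[CEOutcome, CEOutcome, ICERResult]:
    """Run both arms and the pairwise ICER of screening versus standard care."""
    soc = evaluate_strategy("SOC", params, lifetable)
    pws = evaluate_strategy("PWS", params, lifetable)
    return soc, pws, compute_icer(soc, pws)


def _factory_from_params(params: ModelParams, lifetable: LifeTable) -> Callable[[float], ICERResult]:
    def factory(price: float) -> ICERResult:
        trial = params.with_overrides({"test.unit_cost": float(price)})
        return evaluate_icer(trial, lifetable)[2]
    return factory


# ---------------------------------------------------------------------------
# Threshold analysis
# ---------------------------------------------------------------------------

def predict_threshold_price(
    p1: float, w1: float, p2: float, w2: float, wtp: float
) -> float:
    """Threshold price at ``wtp`` from the solver's affine price-WTP model.

    Because incremental cost is affine in the test price while the QALY
    increment is price-independent, the solved threshold price is itself an
    affine function of the WTP level; two known (price, WTP) pairs determine
    the whole line.
    """
    if w1 == w2:
        raise ModelValidationError("WTP anchor points must differ")
    slope = (p2 - p1) / (w2 - w1)
    return p1 + slope * (wtp - w1)


def threshold_price(
    model: Callable[[float], ICERResult],
    wtp: float,
    price_range: tuple[float, float] = (1.0, 811.30),
    tol: float = 1e-6,
) -> ThresholdResult:
    """Solve ICER(price) = WTP for the screening-test price.

    Evaluates the model at the range endpoints, solves the implied linear
    equation, and confirms with one evaluation at the solution (relative
    ICER error <= ``tol``).  If the WTP lies outside the attainable ICER
    range the nearer endpoint is reported with ``attainable = False``.  A
    non-monotone ICER over the range signals a mis-wired strategy and raises.
    """
    lo, hi = price_range
    if not hi > lo:
        raise ModelValidationError(f"empty price range {price_range!r}")
    r_lo, r_hi = model(lo), model(hi)
    if r_lo.delta_effect <= 0 or r_hi.delta_effect <= 0:
        raise ModelValidationError(
            "threshold analysis requires a positive QALY increment for screening"
        )
    i_lo, i_hi = r_lo.icer, r_hi.icer
    evals = [(lo, i_lo), (hi, i_hi)]
    if i_hi <= i_lo:
        raise ModelValidationError(
            f"ICER is not increasing over the price range ({i_lo:.2f} at {lo}, "
            f"{i_hi:.2f} at {hi}); strategy wiring is inconsistent"
        )
    if wtp < i_lo or wtp > i_hi:
        price = lo if abs(wtp - i_lo) <= abs(wtp - i_hi) else hi
        return ThresholdResult(wtp, price, False, tuple(evals))

    price = lo + (wtp - i_lo) * (hi - lo) / (i_hi - i_lo)
    r_mid = model(price)
    evals.append((price, r_mid.icer))
    if abs(r_mid.icer - wtp) > tol * max(abs(wtp), 1.0):
        # affinity violated: fall back to bisection
        a, b = lo, hi
        for _ in range(200):
            m = 0.5 * (a + b)
            r = model(m)
            evals.append((m, r.icer))
            if abs(r.icer - wtp) <= tol * max(abs(wtp), 1.0):
                price = m
                break
            if r.icer < wtp:
                a = m
            else:
                b = m
        else:
            raise ModelValidationError("threshold bisection failed to converge")
        price = m
    return ThresholdResult(wtp, float(price), True, tuple(evals))


# ---------------------------------------------------------------------------
# Deterministic sensitivity analyses
# ---------------------------------------------------------------------------

def one_way(
    model: Callable[[float], ICERResult] | None,
    parameter: str,
    low: float,
    high: float,
    *,
    params: ModelParams | None = None,
    lifetable: LifeTable | None = None,
) -> dict:
    """Two-point one-way sensitivity record for a tornado diagram.

    Either pass a ``model`` callable mapping the parameter value to an
    ICER result, or a params/lifetable pair plus the dotted parameter path.
    """
    if low >= high:
        raise ModelValidationError(f"one-way bounds must satisfy low < high, got {low}, {high}")
    if model is None:
        if params is None or lifetable is None:
            raise ModelValidationError("one_way needs a model callable or params + lifetable")

        def model(value: float) -> ICERResult:
            return evaluate_icer(params.with_overrides({parameter: value}), lifetable)[2]

    r_low, r_high = model(low), model(high)
    return {
        "parameter": parameter, "low": low, "high": high,
        "icer_low": r_low.icer, "icer_high": r_high.icer,
        "raises_icer": "high" if (r_high.icer or 0) >= (r_low.icer or 0) else "low",
    }


def prevalence_sweep(
    params: ModelParams,
    lifetable: LifeTable,
    prevalences: Sequence[float],
    *,
    price_cap: float = 811.30,
    couple_risks: bool = True,
) -> list[dict]:
    """ICER of screening across aneurysm prevalence levels.

    De novo formation and annual rupture risks scale proportionally with
    prevalence relative to the base configuration (``couple_risks``), so a
    higher-prevalence population is also a higher-rupture-burden one.  The
    screening-test price is capped at the mean MRA cost.
    """
    base_prev = params.epidemiology.uia_prevalence_at_entry
    out = []
    for prev in prevalences:
        if not 0.0 < prev < 1.0:
            raise ModelValidationError(f"prevalence must lie in (0, 1), got {prev!r}")
        scale = prev / base_prev
        overrides = {"epidemiology.uia_prevalence_at_entry": float(prev),
                     "test.unit_cost": float(min(params.test.unit_cost, price_cap))}
        if couple_risks:
            epi = params.epidemiology
            overrides["epidemiology.de_novo_annual_incidence"] = min(
                epi.de_novo_annual_incidence * scale, 1.0)
            overrides["epidemiology.annual_rupture_risk_treat_indicated"] = min(
                epi.annual_rupture_risk_treat_indicated * scale, 0.99)
            overrides["epidemiology.annual_rupture_risk_conservative"] = min(
                epi.annual_rupture_risk_conservative * scale, 0.99)
        trial = params.with_overrides(overrides)
        soc, pws, icer = evaluate_icer(trial, lifetable)
        out.append({"prevalence": prev, "icer": icer.as_dict(),
                    "soc": {"cost": soc.cost, "qalys": soc.qalys},
                    "pws": {"cost": pws.cost, "qalys": pws.qalys}})
    return out


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

def _sample_one(dist: DistributionSpec, rng: np.random.Generator) -> float:
    if dist.family == "point":
        if dist.value is None:
            raise ModelValidationError(f"{dist.parameter}: point distribution needs 'value'")
        return float(dist.value)
    if dist.family == "uniform":
        if dist.low is None or dist.high is None or dist.low > dist.high:
            raise ModelValidationError(f"{dist.parameter}: uniform needs low <= high")
        return float(rng.uniform(dist.low, dist.high))
    if dist.mean is None or dist.sd is None:
        raise ModelValidationError(f"{dist.parameter}: {dist.family} needs mean and sd")
    m, s = dist.mean, dist.sd
    if s == 0:
        return float(m)
    if dist.family == "beta":
        if not 0.0 < m < 1.0:
            raise ModelValidationError(f"{dist.parameter}: beta mean must lie in (0, 1)")
        nu = m * (1 - m) / s**2 - 1.0
        if nu <= 0:
            raise ModelValidationError(f"{dist.parameter}: beta sd too large for mean {m}")
        return float(rng.beta(m * nu, (1 - m) * nu))
    if dist.family == "gamma":
        if m <= 0:
            raise ModelValidationError(f"{dist.parameter}: gamma mean must be positive")
        shape = (m / s) ** 2
        return float(rng.gamma(shape, m / shape))
    raise ModelValidationError(f"{dist.parameter}: unknown family {dist.family!r}")


def _rebalance_sah_split(params: ModelParams, overrides: dict[str, float]) -> None:
    """Keep the SAH landing distribution coherent when its pieces are sampled.

    If the favorable share is drawn but the non-favorable split is not, the
    moderate/severe/dead masses are rescaled proportionally so the four-way
    distribution still sums to one.
    """
    key = "sah_outcomes.p_favorable"
    if key not in overrides:
        return
    split_keys = ("p_moderate", "p_severe", "p_dead")
    if any(f"sah_outcomes.{k}" in overrides for k in split_keys):
        return
    sah = params.sah_outcomes
    old_rest = sah.p_moderate + sah.p_severe + sah.p_dead
    new_rest = 1.0 - overrides[key]
    scale = new_rest / old_rest if old_rest > 0 else 0.0
    for k in split_keys:
        overrides[f"sah_outcomes.{k}"] = getattr(sah, k) * scale


def run_psa(
    params: ModelParams,
    lifetable: LifeTable,
    distributions: Sequence[DistributionSpec] | None = None,
    n: int = 1000,
    seed: int = 20240,
) -> PSAResult:
    """Joint Monte Carlo resampling of uncertain parameters.

    Each iteration draws one parameter vector, runs both arms, and records
    (cost, QALYs) per arm.  Deterministic given ``seed``.
    """
    if n < 1:
        raise ModelValidationError("PSA needs n >= 1 iterations")
    if distributions is None:
        distributions = params.analysis.distributions
    rng = np.random.default_rng(seed)
    soc_c = np.empty(n); soc_q = np.empty(n)
    pws_c = np.empty(n); pws_q = np.empty(n)
    for i in range(n):
        overrides = {d.parameter: _sample_one(d, rng) for d in distributions}
        _rebalance_sah_split(params, overrides)
        trial = params.with_overrides(overrides)
        soc = evaluate_strategy("SOC", trial, lifetable)
        pws = evaluate_strategy("PWS", trial, lifetable)
        soc_c[i], soc_q[i] = soc.cost, soc.qalys
        pws_c[i], pws_q[i] = pws.cost, pws.qalys
    return PSAResult(seed=seed, n_iterations=n, soc_cost=soc_c, soc_qalys=soc_q,
                     pws_cost=pws_c, pws_qalys=pws_q)


def ceac(psa: PSAResult, wtp_grid: Sequence[float]) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve of screening.

    For each WTP ``w``, the fraction of iterations in which screening has a
    positive net monetary benefit, ``w * delta_effect - delta_cost > 0``.
    """
    grid = np.asarray(list(wtp_grid), dtype=float)
    if grid.size == 0:
        raise ModelValidationError("WTP grid must be non-empty")
    d_e = psa.pws_qalys - psa.soc_qalys
    d_c = psa.pws_cost - psa.soc_cost
    prob = [(w * d_e - d_c > 0).mean() for w in grid]
    return pd.DataFrame({"wtp": grid, "prob_screening_cost_effective": prob})
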