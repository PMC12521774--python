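"""ICERs, threshold solving, sensitivity analyses, and the PSA."""

import numpy as np
import pytest

from uiascreen.cea import (
    CEOutcome,
    ParameterDistribution,
    _factory_from_params,
    ceac,
    compute_icer,
    evaluate_icer,
    one_way,
    predict_threshold_price,
    prevalence_sweep,
    run_psa,
    threshold_price,
)
from uiascreen.markov import ModelValidationError


class TestComputeIcer:
    def test_printed_arm_values(self):
        """The rounded published arm values imply a ratio of ~165,621 per QALY."""
        soc = CEOutcome("SOC", 3138.72, 22.40)
        pws = CEOutcome("PWS", 23013.24, 22.52)
        r = compute_icer(soc, pws)
        assert r.delta_cost == pytest.approx(19874.52)
        assert r.delta_effect == pytest.approx(0.12)
        assert r.icer == pytest.approx(165621.0, rel=1e-6)
        assert r.status == "ratio"

    def test_dominance_statuses(self):
        ref = CEOutcome("SOC", 1000.0, 10.0)
        assert compute_icer(ref, CEOutcome("PWS", 900.0, 11.0)).status == "dominant"
        assert compute_icer(ref, CEOutcome("PWS", 1100.0, 9.0)).status == "dominated"
        equal = compute_icer(ref, CEOutcome("PWS", 1500.0, 10.0))
        assert equal.status == "equal-effect" and equal.icer is None


class TestThreshold:
    def test_icer_affine_in_test_price(self, lifetable, calibrated_params):
        """Three price evaluations are exactly collinear (costs enter
        linearly and never feed back into transitions)."""
        fac = _factory_from_params(calibrated_params, lifetable)
        prices = np.array([1.0, 300.0, 811.30])
        icers = np.array([fac(p).icer for p in prices])
        slope = (icers[2] - icers[0]) / (prices[2] - prices[0])
        predicted_mid = icers[0] + slope * (prices[1] - prices[0])
        assert abs(predicted_mid - icers[1]) <= 1e-9 * abs(icers[1])

    def test_threshold_prices_increase_with_wtp(self, lifetable, calibrated_params):
        fac = _factory_from_params(calibrated_params, lifetable)
        prices = [threshold_price(fac, w, (1.0, 811.30)).threshold_price
                  for w in (20000.0, 50000.0, 100000.0)]
        assert prices[0] < prices[1] < prices[2]

    def test_solution_confirmed_at_wtp(self, lifetable, calibrated_params):
        fac = _factory_from_params(calibrated_params, lifetable)
        res = threshold_price(fac, 50000.0, (1.0, 811.30))
        assert res.attainable
        assert fac(res.threshold_price).icer == pytest.approx(50000.0, rel=1e-6)
        assert len(res.evaluations) >= 3

    def test_no_dominance_at_any_price(self, lifetable, calibrated_params):
        """Under default parameters no non-negative test price makes
        screening dominant (negative ICER)."""
        fac = _factory_from_params(calibrated_params, lifetable)
        for price in (1e-9, 1.0, 100.0, 811.30):
            r = fac(price)
            assert r.delta_effect > 0
            assert r.icer >= 0.0, price

    def test_unattainable_wtp_reports_endpoint(self, lifetable, calibrated_params):
        fac = _factory_from_params(calibrated_params, lifetable)
        res = threshold_price(fac, 1.0, (1.0, 811.30))
        assert not res.attainable
        assert res.threshold_price == 1.0

    def test_linear_model_predicts_held_out_point(self):
        assert predict_threshold_price(78.56, 20000, 225.72, 50000, 100000) == (
            pytest.approx(470.99, abs=0.02)
        )


class TestOneWay:
    def test_ignored_parameter_leaves_icer_unchanged(self, lifetable, calibrated_params):
        """The conservative-rupture rehab cost of an unreachable class leaves
        the ICER invariant only if the model truly ignores it; use the
        utility of an empty stratum instead: the severe-care cost with a
        zero-severe outcome split."""
        p = calibrated_params.with_overrides({
            "sah_outcomes.p_severe": 0.0, "sah_outcomes.p_dead": 0.345,
            "treatment.p_morbidity_clip": 0.0, "treatment.p_morbidity_endo": 0.0,
        })
        rec = one_way(None, "sah_outcomes.rehab_cost_severe", 1000.0, 90000.0,
                      params=p, lifetable=lifetable)
        assert rec["icer_low"] == pytest.approx(rec["icer_high"], rel=1e-12)

    def test_cost_parameter_weakly_monotone(self, lifetable, calibrated_params):
        rec = one_way(None, "test.unit_cost", 1.0, 811.30,
                      params=calibrated_params, lifetable=lifetable)
        assert rec["icer_high"] > rec["icer_low"]
        assert rec["raises_icer"] == "high"

    def test_rejects_inverted_bounds(self):
        with pytest.raises(ModelValidationError):
            one_way(lambda v: None, "x", 2.0, 1.0)


class TestPrevalenceSweep:
    def test_icer_falls_with_prevalence(self, lifetable, calibrated_params):
        res = prevalence_sweep(calibrated_params, lifetable, [0.023, 0.04, 0.09])
        icers = [r["icer"]["icer"] for r in res]
        assert icers[0] > icers[1] > icers[2]

    def test_vanishing_prevalence_degenerates(self, lifetable, calibrated_params):
        res = prevalence_sweep(calibrated_params, lifetable, [1e-6])
        assert res[0]["icer"]["delta_effect"] == pytest.approx(0.0, abs=1e-4)

    def test_rejects_out_of_range(self, lifetable, calibrated_params):
        with pytest.raises(ModelValidationError):
            prevalence_sweep(calibrated_params, lifetable, [0.0])


class TestPsa:
    def test_point_masses_reproduce_deterministic_run(self, lifetable, calibrated_params):
        soc, pws, _ = evaluate_icer(calibrated_params, lifetable)
        dists = [
            ParameterDistribution(parameter="sah_outcomes.acute_treatment_cost",
                                  family="point",
                                  value=calibrated_params.sah_outcomes.acute_treatment_cost),
            ParameterDistribution(parameter="treatment.clip_cost", family="point",
                                  value=calibrated_params.treatment.clip_cost),
        ]
        res = run_psa(calibrated_params, lifetable, dists, n=5, seed=9)
        assert np.all(res.soc_cost == soc.cost)
        assert np.all(res.pws_qalys == pws.qalys)
        assert res.icer_of_means == pytest.approx(
            (pws.cost - soc.cost) / (pws.qalys - soc.qalys))

    def test_same_seed_bitwise_identical(self, lifetable, calibrated_params):
        a = run_psa(calibrated_params, lifetable, n=4, seed=123)
        b = run_psa(calibrated_params, lifetable, n=4, seed=123)
        for x, y in [(a.soc_cost, b.soc_cost), (a.pws_cost, b.pws_cost),
                     (a.soc_qalys, b.soc_qalys), (a.pws_qalys, b.pws_qalys)]:
            assert np.array_equal(x, y)

    def test_cost_only_means_converge_to_deterministic(self, lifetable, calibrated_params):
        """Arm costs are linear in every cost parameter, so with cost-only
        sampling the PSA mean converges to the deterministic value."""
        soc_det, _, _ = evaluate_icer(calibrated_params, lifetable)
        dists = [d for d in calibrated_params.analysis.distributions
                 if d.family == "gamma"]
        errors = {}
        for n in (10, 100, 1000):
            res = run_psa(calibrated_params, lifetable, dists, n=n, seed=42)
            errors[n] = abs(res.soc_mean[0] - soc_det.cost)
            sd = res.soc_cost.std(ddof=1)
            assert errors[n] <= 4.0 * sd / np.sqrt(n), n

    def test_invalid_distribution_spec(self, lifetable, calibrated_params):
        bad = [ParameterDistribution(parameter="test.sensitivity", family="beta",
                                     mean=1.5, sd=0.1)]
        with pytest.raises(ModelValidationError, match="beta mean"):
            run_psa(calibrated_params, lifetable, bad, n=1, seed=0)
        missing = [ParameterDistribution(parameter="imaging.mra_cost", family="gamma")]
        with pytest.raises(ModelValidationError, match="needs mean and sd"):
            run_psa(calibrated_params, lifetable, missing, n=1, seed=0)


class TestCeac:
    def test_point_mass_cloud_is_step_function(self, lifetable, calibrated_params):
        res = run_psa(calibrated_params, lifetable, [], n=3, seed=0)
        det_icer = evaluate_icer(calibrated_params, lifetable)[2].icer
        curve = ceac(res, [det_icer * 0.5, det_icer * 2.0])
        assert list(curve["prob_screening_cost_effective"]) == [0.0, 1.0]

    def test_limits(self, lifetable, calibrated_params):
        res = run_psa(calibrated_params, lifetable, n=8, seed=2)
        curve = ceac(res, [0.0, 1e12])
        cheaper = float((res.pws_cost < res.soc_cost).mean())
        gains = float((res.pws_qalys > res.soc_qalys).mean())
        assert curve["prob_screening_cost_effective"].iloc[0] == cheaper
        assert curve["prob_screening_cost_effective"].iloc[1] == gains

    def test_empty_grid_rejected(self, lifetable, calibrated_params):
        res = run_psa(calibrated_params, lifetable, [], n=1, seed=0)
        with pytest.raises(ModelValidationError):
            ceac(res, [])
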