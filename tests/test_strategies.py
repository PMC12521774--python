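"""Screening cascade, follow-up schedules, SAH sub-tree, and arm assembly."""

import numpy as np
import pytest

from uiascreen.cea import evaluate_strategy, run_strategy_trace
from uiascreen.markov import HealthState, ModelValidationError
from uiascreen.strategies import (
    DEFAULT_SCHEDULES,
    EpidemiologyParams,
    ImagingCosts,
    SahOutcomeModel,
    ScreeningTest,
    TreatmentParams,
    annualize_risk,
    followup_cost_stream,
    sah_event_subtree,
    screening_cascade,
)

S = HealthState


def make_epi(**kw):
    defaults = dict(
        uia_prevalence_at_entry=0.03,
        annual_rupture_risk_conservative=0.00123,
        annual_rupture_risk_treat_indicated=0.0048,
        fraction_treat_indicated=0.396,
        de_novo_annual_incidence=0.0008,
        incidental_detection_annual_prob=0.02,
        annual_escalation_prob=0.12,
        sah_before_entry_fraction=0.0,
    )
    defaults.update(kw)
    return EpidemiologyParams(**defaults)


def make_treat(**kw):
    defaults = dict(p_clip=0.444, p_endo=0.556, clip_cost=25000, endo_cost=20000,
                    p_death_clip=0.009, p_morbidity_clip=0.045,
                    p_death_endo=0.003, p_morbidity_endo=0.025)
    defaults.update(kw)
    return TreatmentParams(**defaults)


def make_sah(**kw):
    defaults = dict(p_favorable=0.545, p_moderate=0.11, p_severe=0.075, p_dead=0.27,
                    acute_treatment_cost=50000, rehab_cost_healthy=4000,
                    rehab_cost_moderate=25000, rehab_cost_severe=40000,
                    annual_care_cost_moderate=11000, annual_care_cost_severe=48000)
    defaults.update(kw)
    return SahOutcomeModel(**defaults)


class TestAnnualizeRisk:
    def test_closed_form_and_compounding(self):
        a = annualize_risk(0.05, 5)
        assert a == pytest.approx(1 - 0.95 ** 0.2)
        assert a == pytest.approx(0.010206, abs=5e-7)
        # round trip: compounding the annual risk recovers the cumulative one
        assert 1 - (1 - a) ** 5 == pytest.approx(0.05, rel=1e-12)

    @pytest.mark.parametrize("p", [0.0, 0.01, 0.5, 0.999])
    def test_identity_horizon(self, p):
        assert annualize_risk(p, 1) == pytest.approx(p)

    def test_zero_risk(self):
        assert annualize_risk(0.0, 5) == 0.0

    @pytest.mark.parametrize("bad, horizon", [(1.0, 5), (-0.1, 5), (0.5, 0), (0.5, -1)])
    def test_domain_errors(self, bad, horizon):
        with pytest.raises(ModelValidationError):
            annualize_risk(bad, horizon)


class TestScreeningCascade:
    def test_perfect_test_branches(self):
        test = ScreeningTest(sensitivity=1, specificity=1, unit_cost=0)
        p = 0.03
        initial, cost, branches = screening_cascade(
            test, make_epi(uia_prevalence_at_entry=p), ImagingCosts(), make_treat()
        )
        by = {b["branch"]: b["probability"] for b in branches}
        assert by["TP"] == pytest.approx(p)
        assert by["TN"] == pytest.approx(1 - p)
        assert by["FP"] == 0.0 and by["FN"] == 0.0
        assert initial.sum() == pytest.approx(1.0)

    def test_imperfect_test_error_masses(self):
        """MRA-like accuracy at 3% prevalence: FN 0.45%, FP 4.85%."""
        test = ScreeningTest(sensitivity=0.85, specificity=0.95, unit_cost=811.30)
        _, _, branches = screening_cascade(
            test, make_epi(), ImagingCosts(), make_treat()
        )
        by = {b["branch"]: b["probability"] for b in branches}
        assert by["FN"] == pytest.approx(0.0045)
        assert by["FP"] == pytest.approx(0.0485)
        assert sum(by.values()) == pytest.approx(1.0)

    def test_missed_sah_fraction_bypasses_screen(self):
        test = ScreeningTest(sensitivity=1, specificity=1, unit_cost=0)
        initial, _, branches = screening_cascade(
            test, make_epi(sah_before_entry_fraction=0.10), ImagingCosts(), make_treat()
        )
        by = {b["branch"]: b["probability"] for b in branches}
        assert by["BYPASS"] == pytest.approx(0.003)
        assert by["TP"] == pytest.approx(0.027)
        assert initial[S.HEALTHY_WITH_ANEURYSM] == pytest.approx(0.003)

    def test_risk_stratifying_skips_confirmatory_mra(self):
        imaging = ImagingCosts(mra_cost=800, dsa_cost=0)
        treat = make_treat(clip_cost=0, endo_cost=0, p_death_clip=0, p_death_endo=0,
                           p_morbidity_clip=0, p_morbidity_endo=0)
        epi = make_epi()
        plain = ScreeningTest(sensitivity=1, specificity=1, unit_cost=0)
        direct = ScreeningTest(sensitivity=1, specificity=1, unit_cost=0,
                               risk_stratifying=True)
        _, cost_plain, _ = screening_cascade(plain, epi, imaging, treat)
        _, cost_direct, _ = screening_cascade(direct, epi, imaging, treat)
        assert cost_plain == pytest.approx(0.03 * 800)  # one MRA per positive
        assert cost_direct == 0.0


class TestFollowupStreams:
    imaging = ImagingCosts(mra_cost=800.0, cta_cost=650.0, dsa_cost=1500.0)

    def test_post_clip_every_five_years(self):
        stream = followup_cost_stream(DEFAULT_SCHEDULES["post_clip"], self.imaging)
        charged = np.flatnonzero(stream)
        assert list(charged) == [5, 10, 15, 20, 25, 30, 35, 40, 45, 50, 55, 60]
        assert np.all(stream[charged] == 650.0)

    def test_post_coil_binning(self):
        """Discharge in year 0; the 6- and 18-month scans share year 1; then
        36 months and every third year."""
        stream = followup_cost_stream(DEFAULT_SCHEDULES["post_coil"], self.imaging)
        m = 800.0
        assert stream[0] == m
        assert stream[1] == 2 * m
        assert stream[2] == 0.0
        assert stream[3] == m
        assert list(np.flatnonzero(stream[4:]) + 4) == list(range(6, 61, 3))

    def test_untreated_annual_then_biennial(self):
        stream = followup_cost_stream(DEFAULT_SCHEDULES["untreated_uia"], self.imaging)
        charged = list(np.flatnonzero(stream))
        assert charged == [1, 2, 3, 4, 5] + list(range(7, 61, 2))
        assert np.all(stream[np.array(charged)] == 800.0)

    def test_streams_match_calendar_enumeration_oracle(self):
        """Independent calendar enumeration over 60 years, with hand-frozen
        bins for the sub-annual post-coil offsets."""
        oracle = {
            "untreated_uia": {y: 800.0 for y in [1, 2, 3, 4, 5, *range(7, 61, 2)]},
            "post_clip": {y: 650.0 for y in range(5, 61, 5)},
            "post_coil": {0: 800.0, 1: 1600.0, 3: 800.0,
                          **{y: 800.0 for y in range(6, 61, 3)}},
        }
        for ctx, expected in oracle.items():
            stream = followup_cost_stream(DEFAULT_SCHEDULES[ctx], self.imaging)
            got = {int(i): float(v) for i, v in enumerate(stream) if v}
            assert got == expected, ctx

    def test_reusable_test_replaces_mra(self):
        test = ScreeningTest(sensitivity=1, specificity=1, unit_cost=123.0,
                             reusable_in_followup=True, cost_recurring=False)
        stream = followup_cost_stream(DEFAULT_SCHEDULES["untreated_uia"],
                                      self.imaging, test)
        assert stream[1] == 123.0
        # under the recurring wiring the annual test is already paid for
        test_rec = test.model_copy(update={"cost_recurring": True})
        stream_rec = followup_cost_stream(DEFAULT_SCHEDULES["untreated_uia"],
                                          self.imaging, test_rec)
        assert np.all(stream_rec == 0.0)

    def test_unknown_modality_rejected(self):
        from uiascreen.strategies import FollowUpSchedule
        with pytest.raises(Exception):
            FollowUpSchedule(context="untreated_uia", prefix=[(1.0, "PET")])


class TestSahSubtree:
    def test_all_dead_outcome(self):
        outcome = make_sah(p_favorable=0.0, p_moderate=0.0, p_severe=0.0, p_dead=1.0)
        landing, cost = sah_event_subtree(outcome)
        assert landing[S.DEAD] == 1.0
        assert cost == outcome.acute_treatment_cost

    def test_favorable_mass_lands_healthy(self):
        landing, _ = sah_event_subtree(make_sah())
        assert landing[S.HEALTHY_NO_ANEURYSM] == pytest.approx(0.545)
        assert landing.sum() == pytest.approx(1.0)

    def test_zero_cost_model(self):
        outcome = make_sah(acute_treatment_cost=0, rehab_cost_healthy=0,
                           rehab_cost_moderate=0, rehab_cost_severe=0)
        _, cost = sah_event_subtree(outcome)
        assert cost == 0.0

    def test_distribution_must_sum_to_one(self):
        with pytest.raises(Exception, match="sum to 1"):
            make_sah(p_dead=0.5)


class TestAssembledArms:
    def test_zero_prevalence_equalizes_qalys(self, lifetable, calibrated_params):
        """With nothing to detect, both arms produce identical QALYs and the
        cost difference is the screening charge alone."""
        p = calibrated_params.with_overrides({
            "epidemiology.uia_prevalence_at_entry": 0.0,
            "epidemiology.de_novo_annual_incidence": 0.0,
        })
        soc = evaluate_strategy("SOC", p, lifetable)
        pws = evaluate_strategy("PWS", p, lifetable)
        assert pws.qalys == pytest.approx(soc.qalys, abs=1e-12)
        # recurring wiring: the gap equals unit cost times discounted alive-years
        trace = run_strategy_trace("PWS", p, lifetable)
        disc_years = float(
            (trace.accrual_weights(trace.alive)
             * (1.03 ** -np.arange(trace.n_cycles))).sum()
        )
        assert pws.cost - soc.cost == pytest.approx(p.test.unit_cost * disc_years)

    def test_screening_gains_qalys_with_safe_perfect_test(self, lifetable, calibrated_params):
        p = calibrated_params.with_overrides({
            "test.unit_cost": 0.0,
            "treatment.p_death_clip": 0.0, "treatment.p_death_endo": 0.0,
            "treatment.p_morbidity_clip": 0.0, "treatment.p_morbidity_endo": 0.0,
        })
        soc = evaluate_strategy("SOC", p, lifetable)
        pws = evaluate_strategy("PWS", p, lifetable)
        assert pws.qalys >= soc.qalys

    def test_costs_monotone_qalys_invariant(self, lifetable, calibrated_params):
        """Raising any unit cost weakly raises that arm's total cost and
        never changes its QALYs."""
        base = evaluate_strategy("PWS", calibrated_params, lifetable)
        for key in ["imaging.mra_cost", "imaging.dsa_cost", "treatment.clip_cost",
                    "sah_outcomes.acute_treatment_cost", "test.unit_cost"]:
            cur = calibrated_params
            node = cur
            for part in key.split(".")[:-1]:
                node = getattr(node, part)
            value = getattr(node, key.split(".")[-1])
            bumped = evaluate_strategy(
                "PWS", calibrated_params.with_overrides({key: value * 1.5}), lifetable
            )
            assert bumped.cost >= base.cost - 1e-9, key
            assert bumped.qalys == pytest.approx(base.qalys, abs=1e-12), key

    def test_missing_parameter_names_key(self, calibrated_params):
        from uiascreen.config import ConfigError
        with pytest.raises(ConfigError, match="unknown parameter path"):
            calibrated_params.with_overrides({"test.not_a_field": 1.0})
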