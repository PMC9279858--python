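import itertools
import math

import numpy as np
import pytest

from credmeta import (
    AnalysisConfig,
    InsufficientStudiesError,
    begg_test,
    egger_test,
    excess_significance,
    run_association,
    sensitivity_suite,
    assess_bias,
)
from credmeta.meta import pool_fixed
from credmeta.simulate import SimulationConfig, simulate_association


class TestEgger:
    def test_hand_computed_intercept(self, effect_factory):
        effects = [
            effect_factory(0.1, 0.1),
            effect_factory(0.3, 0.2),
            effect_factory(0.5, 0.3),
        ]
        intercept, _ = egger_test(effects)
        assert intercept == pytest.approx(2.00, abs=1e-8)

    def test_matches_generic_ols_oracle(self, effect_factory, rng):
        for _ in range(20):
            k = int(rng.integers(3, 12))
            effects = [
                effect_factory(float(rng.normal(0, 0.5)), float(rng.uniform(0.05, 0.5)))
                for _ in range(k)
            ]
            x = np.array([1 / e.se for e in effects])
            y = np.array([e.log_or / e.se for e in effects])
            slope, icpt = np.polyfit(x, y, 1)
            assert egger_test(effects)[0] == pytest.approx(icpt, abs=1e-8)

    def test_insufficient_studies(self, effect_factory):
        with pytest.raises(InsufficientStudiesError):
            egger_test([effect_factory(0.1, 0.1), effect_factory(0.2, 0.2)])

    def test_null_calibration(self):
        """Unbiased simulated meta-analyses reject at roughly the nominal 10%."""
        reps, hits = 2000, 0
        for i in range(reps):
            dataset = simulate_association(
                SimulationConfig(
                    n_studies=10,
                    true_or=1.0,
                    cases_range=(300, 800),
                    controls_range=(300, 800),
                    seed=500_000 + i,
                )
            )
            res = run_association(dataset.records)
            if egger_test(list(res.effects))[1] < 0.1:
                hits += 1
        assert hits / reps == pytest.approx(0.10, abs=0.04)


def _kendall_oracle(u, v):
    s = 0
    for (u1, v1), (u2, v2) in itertools.combinations(zip(u, v), 2):
        s += np.sign(u1 - u2) * np.sign(v1 - v2)
    n = len(u)
    return s / (n * (n - 1) / 2)


class TestBegg:
    def test_concordant_ranks_give_tau_one(self, effect_factory):
        # effects rise steeply with variance so standardized deviations stay ordered
        effects = [
            effect_factory(0.0, 0.10),
            effect_factory(1.0, 0.20),
            effect_factory(2.5, 0.40),
            effect_factory(5.0, 0.80),
        ]
        tau, _ = begg_test(effects)
        assert tau == pytest.approx(1.0)

    def test_mirrored_effects_give_tau_minus_one(self, effect_factory):
        # negating every effect negates the standardized deviations exactly
        effects = [
            effect_factory(0.0, 0.10),
            effect_factory(-1.0, 0.20),
            effect_factory(-2.5, 0.40),
            effect_factory(-5.0, 0.80),
        ]
        tau, _ = begg_test(effects)
        assert tau == pytest.approx(-1.0)

    def test_matches_exhaustive_pair_counting(self, effect_factory, rng):
        for _ in range(25):
            k = int(rng.integers(4, 7))
            effects = [
                effect_factory(float(rng.normal(0, 0.4)), float(rng.uniform(0.05, 0.5)))
                for _ in range(k)
            ]
            pooled, pooled_se = pool_fixed(effects)
            u = [
                (e.log_or - pooled) / math.sqrt(e.se**2 - pooled_se**2)
                for e in effects
            ]
            v = [e.se**2 for e in effects]
            tau, _ = begg_test(effects)
            assert tau == pytest.approx(_kendall_oracle(u, v), abs=1e-10)


class TestExcessSignificance:
    def test_null_pooled_effect_gives_alpha_power(self, effect_factory):
        effects = [effect_factory(0.0, s) for s in (0.1, 0.2, 0.3)]
        res = excess_significance(effects, 0.0)
        assert res.expected == pytest.approx(3 * 0.05)

    def test_saturated_power_no_excess(self, effect_factory):
        effects = [effect_factory(2.0, 0.1, f"s{i}") for i in range(4)]
        res = excess_significance(effects, 2.0)
        assert res.observed == 4
        assert res.expected == pytest.approx(4.0, abs=1e-6)
        assert not res.excess

    def test_expected_monotone_in_pooled_effect(self, effect_factory):
        effects = [effect_factory(0.2, s) for s in (0.1, 0.15, 0.25)]
        expected = [
            excess_significance(effects, mu).expected for mu in (0.0, 0.1, 0.2, 0.4)
        ]
        assert all(a < b for a, b in zip(expected, expected[1:]))

    def test_unbiased_sets_rarely_flagged(self):
        reps, hits = 300, 0
        for i in range(reps):
            dataset = simulate_association(
                SimulationConfig(n_studies=6, true_or=1.4, seed=700_000 + i)
            )
            res = run_association(dataset.records)
            exc = excess_significance(list(res.effects), res.log_or)
            hits += exc.excess
        assert hits / reps <= 0.12


class TestSensitivity:
    def test_concordant_strong_effects_are_robust(self):
        dataset = simulate_association(
            SimulationConfig(
                n_studies=5,
                true_or=2.0,
                cases_range=(1000, 1500),
                controls_range=(1000, 1500),
                seed=42,
            )
        )
        report = sensitivity_suite(dataset.records)
        assert report.applicable and report.robust

    def test_single_driver_study_loses_significance(self, record_factory):
        # three near-null small studies plus one large study carrying the signal
        small_case, small_ctrl = (48, 42, 10), (49, 42, 9)
        recs = [
            record_factory(case=small_case, ctrl=small_ctrl, study_id="a", year=2008),
            record_factory(case=small_case, ctrl=small_ctrl, study_id="b", year=2009),
            record_factory(case=small_case, ctrl=small_ctrl, study_id="d", year=2011),
            record_factory(
                case=(430, 435, 135), ctrl=(490, 420, 90), study_id="c", year=2010
            ),
        ]
        base = run_association(recs)
        assert base.significant and base.model == "fixed"
        report = sensitivity_suite(recs)
        assert report.leave_one_out_loss
        # re-analysis without the driver confirms the loss directly
        assert not run_association(recs[:3]).significant

    def test_earliest_year_tie_drops_all_tied_studies(self, record_factory):
        strong_case, ctrl = (300, 450, 250), (400, 440, 160)
        recs = [
            record_factory(case=strong_case, ctrl=ctrl, study_id="a", year=2007),
            record_factory(case=strong_case, ctrl=ctrl, study_id="b", year=2007),
            record_factory(case=strong_case, ctrl=ctrl, study_id="c", year=2010),
            record_factory(case=strong_case, ctrl=ctrl, study_id="d", year=2011),
            record_factory(case=strong_case, ctrl=ctrl, study_id="e", year=2012),
        ]
        report = sensitivity_suite(recs)
        # both 2007 studies removed together leaves k=3: evaluable, no loss
        assert "first_study" not in report.not_evaluable
        assert not report.first_study_loss

    def test_non_significant_base_not_applicable(self, record_factory):
        recs = [
            record_factory(case=(50, 40, 10), ctrl=(50, 40, 10), study_id=f"s{i}")
            for i in range(3)
        ]
        report = sensitivity_suite(recs)
        assert not report.applicable
        assert not (
            report.leave_one_out_loss or report.first_study_loss or report.hwe_loss
        )


def test_assessment_aggregates_signals():
    dataset = simulate_association(
        SimulationConfig(
            n_studies=6,
            true_or=1.8,
            cases_range=(1000, 2000),
            controls_range=(1000, 2000),
            seed=9,
        )
    )
    meta = run_association(dataset.records)
    assessment = assess_bias(dataset.records, meta)
    expected = (
        assessment.egger_p < 0.1
        or assessment.begg_p < 0.1
        or assessment.excess.excess
        or assessment.sensitivity.leave_one_out_loss
        or assessment.sensitivity.first_study_loss
        or assessment.sensitivity.hwe_loss
    )
    assert assessment.any_bias_signal == expected
    assert -1.0 <= assessment.begg_tau <= 1.0
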