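"""Effect-size transforms and the joint distribution of stage statistics."""

import numpy as np
import pytest

from seamsim import (
    EffectSpec,
    SampleSizePlan,
    binary_effect_statistic,
    build_model_subpop,
    build_model_treatsel,
    cumulative_statistic,
    draw_statistics,
    normal_effect_statistic,
    tte_effect_statistic,
    tte_expected_events,
)
from seamsim.model import covariance_factor, effect_statistic

from conftest import patient_level_subpop_cov, patient_level_treatsel_cov


class TestEffectTransforms:
    @pytest.mark.parametrize("n, theta, expected", [
        (100, 0.68, 4.8), (100, 0.82, 5.8), (100, 0.95, 6.7), (100, 0.91, 6.4),
        (40, 0.68, 3.0), (40, 0.82, 3.7), (40, 0.95, 4.2), (40, 0.91, 4.1),
    ])
    def test_normal_statistic_matches_printed_expectations(self, n, theta, expected):
        assert round(float(normal_effect_statistic(n, theta)), 1) == expected

    def test_normal_statistic_null_and_monotonicity(self):
        assert normal_effect_statistic(73, 0.0) == 0.0
        assert normal_effect_statistic(200, 0.5) > normal_effect_statistic(100, 0.5)
        with pytest.raises(ValueError):
            normal_effect_statistic(0, 0.5)

    def test_tte_expected_events_closed_form(self):
        # hazard-ratio dialect: control hazard 1, unit follow-up
        expected = 30 * (1 - np.exp(-1)) + 30 * (1 - np.exp(-0.6))
        got = tte_expected_events(30, 1.0, 0.6, "hazard-ratio")
        assert got == pytest.approx(expected)
        assert got == pytest.approx(32.50, abs=0.005)
        big = tte_expected_events(300, 1.0, 0.9, "hazard-ratio")
        assert big == pytest.approx(300 * (2 - np.exp(-1) - np.exp(-0.9)))
        # equal arms under the minus-log-hazard dialect
        null = tte_expected_events(50, 0.0, 0.0, "minus-log-hazard")
        assert null == pytest.approx(2 * 50 * (1 - np.exp(-1)))
        with pytest.raises(ValueError):
            tte_expected_events(30, 1.0, -0.5, "hazard-ratio")
        with pytest.raises(ValueError):
            tte_expected_events(30, 0.0, 0.0, "weibull")

    @pytest.mark.parametrize("n, hr, expected", [
        (30, 0.6, -1.46),   # stage-1 subgroup slot of the oncology design
        (100, 0.9, -0.58),  # stage-1 full-population slot
        (200, 0.6, -3.76),  # enriched stage-2 subgroup slot
        (300, 0.9, -1.01),  # stage-2 full-population slot
        (90, 0.6, -2.52),   # stage-2 subgroup slot under co-primary continuation
    ])
    def test_tte_statistic_matches_printed_expectations(self, n, hr, expected):
        z = tte_effect_statistic(n, 1.0, hr, "hazard-ratio")
        assert round(float(z), 2) == expected

    def test_tte_statistic_null_and_sign(self):
        assert tte_effect_statistic(50, 1.0, 1.0, "hazard-ratio") == 0.0
        # beneficial treatment (HR < 1) gives a negative natural statistic
        assert tte_effect_statistic(50, 1.0, 0.7, "hazard-ratio") < 0
        # minus-log-hazard dialect: positive effect is beneficial
        assert tte_effect_statistic(50, 0.0, 0.3, "minus-log-hazard") > 0

    def test_binary_statistic_against_two_proportion_oracle(self):
        # independent oracle: log odds ratio over the 2x2 SE from expected cells
        sm = pytest.importorskip("statsmodels.stats.contingency_tables")
        for n, r0, rk in [(300, 0.50, 0.40), (100, 0.50, 0.45)]:
            table = sm.Table2x2([[n * (1 - rk), n * rk], [n * (1 - r0), n * r0]])
            oracle = table.log_oddsratio / np.sqrt(
                np.sum(1.0 / np.asarray(table.table, float)))
            assert binary_effect_statistic(n, r0, rk) == pytest.approx(oracle, abs=1e-12)

    def test_binary_statistic_frozen_values(self):
        assert binary_effect_statistic(300, 0.50, 0.40) == pytest.approx(2.4575, abs=2e-4)
        assert binary_effect_statistic(100, 0.50, 0.45) == pytest.approx(0.7078, abs=2e-4)
        assert binary_effect_statistic(150, 0.3, 0.3) == 0.0
        assert binary_effect_statistic(300, 0.50, 0.40) > 0  # lower rate is better
        with pytest.raises(ValueError):
            binary_effect_statistic(100, 0.0, 0.5)


class TestEffectSpecValidation:
    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            EffectSpec(arm_effects_early=(0.1, 0.2), arm_effects_final=(0.1,))

    def test_binary_rates_must_be_probabilities(self):
        with pytest.raises(ValueError):
            EffectSpec(arm_effects_early=(0.1,), arm_effects_final=(1.2,),
                       outcome_final="B", control_final=0.5)

    def test_binary_requires_control_rate(self):
        with pytest.raises(ValueError, match="control event rate"):
            EffectSpec(arm_effects_early=(0.1,), arm_effects_final=(0.4,),
                       outcome_final="B")

    def test_subgroup_tte_control_defaults_to_unit_hazard(self):
        spec = EffectSpec(arm_effects_early=(0.6, 0.9), arm_effects_final=(0.6, 0.9),
                          outcome_early="T", outcome_final="T", dialect="subgroup")
        assert spec.control_early == 1.0
        assert spec.control_final == 1.0

    def test_correlation_bounds(self):
        with pytest.raises(ValueError, match="correlation"):
            EffectSpec(arm_effects_early=(0.1,), arm_effects_final=(0.1,), corr=1.5)


class TestTreatmentSelectionModel:
    def test_stage2_increment_means_match_printed_values(self, copd_effects, copd_plan):
        model = build_model_treatsel(copd_effects, copd_plan)
        stage2 = model.mean[8:]
        assert [round(v, 1) for v in stage2] == [1.6, 2.1, 2.8, 2.4]

    def test_structure_at_zero_correlation(self, copd_plan):
        effects = EffectSpec(arm_effects_early=(0.1, 0.2), arm_effects_final=(0.1, 0.2),
                             corr=0.0)
        model = build_model_treatsel(effects, copd_plan)
        corr = model.cov
        assert corr[0, 2] == 0.0            # E_1 vs F1_1
        assert corr[0, 1] == pytest.approx(0.5)  # between arms, lambda = 1
        assert np.allclose(np.diag(corr), 1.0)

    def test_covariance_psd_and_symmetric(self, copd_effects, copd_plan):
        model = build_model_treatsel(copd_effects, copd_plan)
        assert np.allclose(model.cov, model.cov.T)
        assert np.min(np.linalg.eigvalsh(model.cov)) > -1e-12

    def test_matches_patient_level_simulation(self):
        """The Kronecker covariance equals the shared-control patient-level one."""
        effects = EffectSpec(arm_effects_early=(0.0, 0.0), arm_effects_final=(0.0, 0.0),
                             corr=0.4)
        plan = SampleSizePlan(n1=6, n2=6)
        model = build_model_treatsel(effects, plan)
        empirical = patient_level_treatsel_cov(
            n_per_arm=6, n_arms=2, rho=0.4, n_rep=200_000, seed=42)
        assert np.max(np.abs(empirical - model.cov)) < 0.012

    def test_group_sequential_correlation_of_cumulative_statistic(self, copd_effects,
                                                                  copd_plan):
        """corr(F1, Fcum) = sqrt(n1/(n1+n2)) via information weighting."""
        model = build_model_treatsel(copd_effects, copd_plan)
        rng = np.random.default_rng(5)
        draws = draw_statistics(model, rng, size=200_000).values
        f1, f2 = draws[:, 4], draws[:, 8]
        info1, info2 = model.info[4], model.info[8]
        fcum = cumulative_statistic(f1, f2, info1, info2)
        target = np.sqrt(copd_plan.n1 / (copd_plan.n1 + copd_plan.n2))
        assert np.corrcoef(f1, fcum)[0, 1] == pytest.approx(target, abs=0.01)


class TestSubgroupModel:
    def test_nested_correlation_is_sqrt_information_ratio(self, oncology_effects,
                                                          oncology_plan):
        model = build_model_subpop(oncology_effects, oncology_plan)
        ratio = model.info[2] / model.info[3]
        assert model.cov[2, 3] == pytest.approx(np.sqrt(ratio))
        # events scale the information, so the ratio is below the prevalence here
        assert ratio < oncology_plan.prevalence + 0.05

    def test_continuation_controls_stage2_subgroup_information(self, oncology_effects,
                                                               oncology_plan):
        both = build_model_subpop(oncology_effects, oncology_plan, "both")
        sub = build_model_subpop(oncology_effects, oncology_plan, "subgroup-only")
        assert round(both.mean[4], 2) == -2.52   # n2 * tau = 90 per arm
        assert round(sub.mean[4], 2) == -3.76    # enriched to 200 per arm
        assert round(both.mean[5], 2) == -1.01

    def test_degenerate_prevalence_duplicates_populations(self, oncology_effects):
        plan = SampleSizePlan(n1=100, n2=300, prevalence=1.0 - 1e-9)
        effects = EffectSpec(arm_effects_early=(0.9, 0.9), arm_effects_final=(0.9, 0.9),
                             outcome_early="T", outcome_final="T", dialect="subgroup")
        model = build_model_subpop(effects, plan)
        assert model.cov[0, 1] == pytest.approx(1.0, abs=1e-6)
        assert model.mean[0] == pytest.approx(model.mean[1], abs=1e-6)

    def test_matches_patient_level_simulation(self):
        effects = EffectSpec(arm_effects_early=(0.0, 0.0), arm_effects_final=(0.0, 0.0),
                             corr=0.5, dialect="subgroup")
        plan = SampleSizePlan(n1=10, n2=10, prevalence=0.3)
        model = build_model_subpop(effects, plan)
        empirical = patient_level_subpop_cov(
            n_per_arm=10, prevalence=0.3, rho=0.5, n_rep=200_000, seed=7)
        assert np.max(np.abs(empirical - model.cov[:4, :4])) < 0.012


class TestDrawStatistics:
    def test_deterministic_given_state(self, copd_effects, copd_plan):
        model = build_model_treatsel(copd_effects, copd_plan)
        a = draw_statistics(model, np.random.default_rng(123), size=50).values
        b = draw_statistics(model, np.random.default_rng(123), size=50).values
        assert np.array_equal(a, b)

    def test_moments_converge_to_model(self, copd_effects, copd_plan):
        model = build_model_treatsel(copd_effects, copd_plan)
        draws = draw_statistics(model, np.random.default_rng(9), size=100_000).values
        assert np.max(np.abs(draws.mean(axis=0) - model.mean)) < 3 * np.sqrt(1 / 1e5) * 3
        emp = np.corrcoef(draws.T)
        assert emp[0, 4] == pytest.approx(0.4, abs=0.01)  # corr(E_k, F1_k) = rho

    def test_singular_covariance_uses_eigen_factor(self):
        # corr = 1: early and final stage-1 statistics coincide exactly
        effects = EffectSpec(arm_effects_early=(0.3, 0.4), arm_effects_final=(0.3, 0.4),
                             corr=1.0)
        plan = SampleSizePlan(n1=50, n2=50)
        model = build_model_treatsel(effects, plan)
        factor = covariance_factor(model.cov)
        assert np.allclose(factor @ factor.T, model.cov, atol=1e-10)
        draws = draw_statistics(model, np.random.default_rng(3), size=100).values
        assert np.allclose(draws[:, :2], draws[:, 2:4], atol=1e-7)


def test_effect_statistic_dispatch_consistency():
    mean, info = effect_statistic("N", "treatment", 100, 0.0, 0.5)
    assert mean == pytest.approx(normal_effect_statistic(100, 0.5))
    assert info == pytest.approx(50.0)
    mean_t, info_t = effect_statistic("T", "subgroup", 30, 1.0, 0.6)
    assert mean_t == pytest.approx(tte_effect_statistic(30, 1.0, 0.6, "hazard-ratio"))
    assert info_t == pytest.approx(tte_expected_events(30, 1.0, 0.6, "hazard-ratio") / 4)
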