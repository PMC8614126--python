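import numpy as np
import pytest

from seamsim import EffectSpec, SampleSizePlan


@pytest.fixture
def copd_effects():
    """Five-arm COPD dose-selection effects (normal early and final outcomes)."""
    return EffectSpec(
        arm_effects_early=(0.68, 0.82, 0.95, 0.91),
        arm_effects_final=(0.13, 0.17, 0.23, 0.20),
        corr=0.4,
        dialect="treatment",
    )


@pytest.fixture
def copd_plan():
    return SampleSizePlan(n1=100, n2=300)


@pytest.fixture
def oncology_effects():
    """Oncology enrichment effects: hazard ratios 0.6 (subgroup) / 0.9 (full)."""
    return EffectSpec(
        arm_effects_early=(0.6, 0.9),
        arm_effects_final=(0.6, 0.9),
        outcome_early="T",
        outcome_final="T",
        corr=0.5,
        dialect="subgroup",
    )


@pytest.fixture
def oncology_plan():
    return SampleSizePlan(n1=100, n2=300, enrich=200, prevalence=0.3)


def patient_level_treatsel_cov(n_per_arm, n_arms, rho, n_rep, seed):
    """Empirical covariance of shared-control z statistics from patient data.

    Simulates bivariate-normal (early, final) outcomes per patient in a
    control arm and ``n_arms`` experimental arms under the global null,
    forms the standardized statistics sqrt(n/2)*(mean_k - mean_0) for
    both endpoints and both disjoint stage cohorts, and returns the
    6-slot-per-... empirical covariance in the package's slot order
    (E_1..E_K, F1_1..F1_K, F2_1..F2_K) with equal stage cohorts.
    """
    rng = np.random.default_rng(seed)
    c = np.sqrt(1.0 - rho ** 2)

    def cohort_stats():
        early = rng.standard_normal((n_rep, n_arms + 1, n_per_arm))
        final = rho * early + c * rng.standard_normal((n_rep, n_arms + 1, n_per_arm))
        em = early.mean(axis=2)
        fm = final.mean(axis=2)
        scale = np.sqrt(n_per_arm / 2.0)
        return (scale * (em[:, 1:] - em[:, :1]),
                scale * (fm[:, 1:] - fm[:, :1]))

    e1, f1 = cohort_stats()
    _, f2 = cohort_stats()  # disjoint stage-2 cohort
    stats = np.concatenate([e1, f1, f2], axis=1)
    return np.cov(stats.T)


def patient_level_subpop_cov(n_per_arm, prevalence, rho, n_rep, seed):
    """Empirical covariance of nested subgroup/full-population z statistics.

    One experimental arm versus control, normal outcomes, null effects;
    the subgroup is the first ``n_per_arm * prevalence`` patients of
    each arm. Returns the empirical covariance of
    (E_S, E_F, F1_S, F1_F) computed from one patient cohort.
    """
    rng = np.random.default_rng(seed)
    c = np.sqrt(1.0 - rho ** 2)
    n_sub = int(round(n_per_arm * prevalence))
    early = rng.standard_normal((n_rep, 2, n_per_arm))
    final = rho * early + c * rng.standard_normal((n_rep, 2, n_per_arm))

    def z_stat(x, n):
        m = x[:, :, :n].mean(axis=2)
        return np.sqrt(n / 2.0) * (m[:, 1] - m[:, 0])

    stats = np.stack([
        z_stat(early, n_sub), z_stat(early, n_per_arm),
        z_stat(final, n_sub), z_stat(final, n_per_arm),
    ], axis=1)
    return np.cov(stats.T)
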