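"""Simulation model: expected z statistics and their joint distribution.

Two-stage seamless phase II/III designs compare either K experimental
arms against a shared control (treatment selection) or a single
experimental treatment against control both in a predefined subgroup and
in the full population (subgroup selection / adaptive enrichment).

Instead of simulating individual patients, the package simulates the
standardized score statistics ``S_kj = theta_hat_kj * sqrt(I_kj)`` (the
treatment-effect estimate scaled by the square root of its Fisher
information) directly from their joint multivariate normal distribution.
Interim selection may be informed by an early outcome while hypothesis
testing uses the final (primary) outcome, so each stage carries
statistics for both endpoints, correlated through the within-patient
early--final correlation ``corr``.

Expected statistics per outcome type (``theta = mu_k - mu_0``):

* normal (``N``): ``sqrt(n/2) * theta`` with ``theta`` a standardized
  mean difference;
* time-to-event (``T``): ``sqrt(o/4) * delta`` where ``o`` is the
  expected total number of events in the two arms under an exponential
  model and ``delta`` is the log hazard-ratio scale effect (see the two
  dialects below);
* binary (``B``): log odds ratio divided by the usual 2x2 standard
  error, with cell counts replaced by their expectations.

Time-to-event effects come in two dialects. The treatment-selection
driver interprets effects as minus log hazard rates, giving event
probabilities ``1 - exp(-exp(-mu))`` per arm. The subgroup driver
interprets them as hazard ratios relative to a control hazard (default
1) with unit follow-up, giving event probabilities ``1 - exp(-h0)`` and
``1 - exp(-h0*HR)``; on that dialect a beneficial treatment produces a
*negative* expected statistic, and the inference code canonicalizes the
sign (larger = better) before testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "NORMAL",
    "TTE",
    "BINARY",
    "EffectSpec",
    "SampleSizePlan",
    "CovarianceModel",
    "StageStatistics",
    "normal_effect_statistic",
    "tte_expected_events",
    "tte_effect_statistic",
    "binary_effect_statistic",
    "effect_statistic",
    "canonical_sign",
    "build_model_treatsel",
    "build_model_subpop",
    "draw_statistics",
    "covariance_factor",
    "cumulative_statistic",
]

NORMAL = "N"
TTE = "T"
BINARY = "B"
OUTCOME_TYPES = (NORMAL, TTE, BINARY)

#: time-to-event effect dialects
MINUS_LOG_HAZARD = "minus-log-hazard"  # treatment-selection driver
HAZARD_RATIO = "hazard-ratio"  # subgroup driver

_PSD_TOL = 1e-9


# ---------------------------------------------------------------------------
# effect-size transforms
# ---------------------------------------------------------------------------


def normal_effect_statistic(n, theta):
    """Expected z statistic ``sqrt(n/2) * theta`` for a normal outcome.

    ``n`` is the per-arm sample size and ``theta`` the standardized mean
    difference versus control.
    """
    n = np.asarray(n, dtype=float)
    if np.any(n < 1):
        raise ValueError("per-arm sample size must be >= 1")
    return np.sqrt(n / 2.0) * np.asarray(theta, dtype=float)


def tte_expected_events(n, mu0=0.0, muk=0.0, dialect=MINUS_LOG_HAZARD):
    """Expected total number of events across the control and one arm.

    Under ``minus-log-hazard`` the per-arm event probability is
    ``1 - exp(-exp(-mu))``.  Under ``hazard-ratio`` the control hazard is
    ``mu0`` (default 1) with unit follow-up, the arm hazard ``mu0*muk``,
    giving ``n*(1 - exp(-mu0)) + n*(1 - exp(-mu0*muk))``.  Events are
    expectations, not integers.
    """
    n = np.asarray(n, dtype=float)
    if np.any(n < 1):
        raise ValueError("per-arm sample size must be >= 1")
    if dialect == MINUS_LOG_HAZARD:
        p0 = 1.0 - np.exp(-np.exp(-np.asarray(mu0, dtype=float)))
        pk = 1.0 - np.exp(-np.exp(-np.asarray(muk, dtype=float)))
    elif dialect == HAZARD_RATIO:
        h0 = np.asarray(mu0, dtype=float)
        hr = np.asarray(muk, dtype=float)
        if np.any(h0 <= 0):
            raise ValueError("control hazard must be positive")
        if np.any(hr <= 0):
            raise ValueError("hazard ratio must be positive")
        p0 = 1.0 - np.exp(-h0)
        pk = 1.0 - np.exp(-h0 * hr)
    else:
        raise ValueError(f"unknown time-to-event dialect: {dialect!r}")
    return n * p0 + n * pk


def tte_effect_statistic(n, mu0=0.0, muk=0.0, dialect=MINUS_LOG_HAZARD):
    """Expected z statistic ``sqrt(o/4) * delta`` for a time-to-event outcome.

    ``delta`` is ``muk - mu0`` on the minus-log-hazard dialect (positive
    is better) or ``log(muk)`` (the log hazard ratio; negative is
    better) on the hazard-ratio dialect.
    """
    o = tte_expected_events(n, mu0, muk, dialect)
    if dialect == MINUS_LOG_HAZARD:
        delta = np.asarray(muk, dtype=float) - np.asarray(mu0, dtype=float)
    else:
        delta = np.log(np.asarray(muk, dtype=float))
    return np.sqrt(o / 4.0) * delta


def binary_effect_statistic(n, r0, rk):
    """Expected log-odds-ratio z statistic for a binary outcome.

    Event rates ``r0`` (control) and ``rk`` (arm) are converted to minus
    log odds ``mu = log((1-r)/r)``; the expected number of events in a
    group of size ``n`` is ``n*r``.  The statistic is positive when the
    arm has the lower event rate.
    """
    n = np.asarray(n, dtype=float)
    r0 = np.asarray(r0, dtype=float)
    rk = np.asarray(rk, dtype=float)
    if np.any(n < 1):
        raise ValueError("per-arm sample size must be >= 1")
    if np.any((r0 <= 0) | (r0 >= 1)) or np.any((rk <= 0) | (rk >= 1)):
        raise ValueError("event rates must lie strictly between 0 and 1")
    mu0 = np.log((1.0 - r0) / r0)
    muk = np.log((1.0 - rk) / rk)
    o0 = n * r0
    ok = n * rk
    se = np.sqrt(1.0 / ok + 1.0 / (n - ok) + 1.0 / o0 + 1.0 / (n - o0))
    return (muk - mu0) / se


def _binary_info(n, r0, rk):
    n = np.asarray(n, dtype=float)
    o0 = np.asarray(n * r0, dtype=float)
    ok = np.asarray(n * rk, dtype=float)
    var = 1.0 / ok + 1.0 / (n - ok) + 1.0 / o0 + 1.0 / (n - o0)
    return 1.0 / var


def effect_statistic(outcome, dialect, n, control, effect):
    """Expected statistic and information for one slot.

    Returns ``(mean, info)`` on the natural (un-canonicalized) scale.
    ``dialect`` is ``"treatment"`` or ``"subgroup"`` and fixes how
    time-to-event and binary effects are read (see module docstring).
    """
    if outcome == NORMAL:
        return normal_effect_statistic(n, np.asarray(effect, float) - control), np.asarray(n, float) / 2.0
    if outcome == TTE:
        dl = MINUS_LOG_HAZARD if dialect == "treatment" else HAZARD_RATIO
        o = tte_expected_events(n, control, effect, dl)
        return tte_effect_statistic(n, control, effect, dl), o / 4.0
    if outcome == BINARY:
        return binary_effect_statistic(n, control, effect), _binary_info(n, control, effect)
    raise ValueError(f"unknown outcome type: {outcome!r}")


def canonical_sign(outcome, dialect):
    """Sign flipping a natural statistic to the larger-is-better scale.

    Only the subgroup driver's hazard-ratio dialect produces statistics
    where smaller is better; every other transform is already oriented
    with larger = better.
    """
    return -1.0 if (outcome == TTE and dialect == "subgroup") else 1.0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EffectSpec:
    """Clinical effect sizes on the early and final outcomes.

    ``arm_effects_*`` hold the per-arm effects (K entries for treatment
    selection; the (subgroup, full-population) pair for subgroup
    selection).  ``control_*`` default to 0, except on the subgroup
    driver's time-to-event dialect where the control entry is the
    baseline hazard (default 1) and arm entries are hazard ratios, and
    for binary outcomes where a control event rate is required.
    """

    arm_effects_early: tuple
    arm_effects_final: tuple
    outcome_early: str = NORMAL
    outcome_final: str = NORMAL
    control_early: float | None = None
    control_final: float | None = None
    corr: float = 0.0
    dialect: str = "treatment"

    def __post_init__(self):
        object.__setattr__(self, "arm_effects_early", tuple(float(x) for x in self.arm_effects_early))
        object.__setattr__(self, "arm_effects_final", tuple(float(x) for x in self.arm_effects_final))
        if self.dialect not in ("treatment", "subgroup"):
            raise ValueError(f"unknown dialect: {self.dialect!r}")
        if self.outcome_early not in OUTCOME_TYPES or self.outcome_final not in OUTCOME_TYPES:
            raise ValueError("outcome types must be one of 'N', 'T', 'B'")
        if len(self.arm_effects_early) != len(self.arm_effects_final):
            raise ValueError("early and final effect vectors must have equal length")
        if self.n_arms < 1:
            raise ValueError("at least one experimental arm is required")
        if not -1.0 <= self.corr <= 1.0:
            raise ValueError("early-final correlation must lie in [-1, 1]")
        object.__setattr__(self, "control_early", self._default_control(self.outcome_early, self.control_early))
        object.__setattr__(self, "control_final", self._default_control(self.outcome_final, self.control_final))
        for outcome, control, arms in (
            (self.outcome_early, self.control_early, self.arm_effects_early),
            (self.outcome_final, self.control_final, self.arm_effects_final),
        ):
            if outcome == BINARY:
                rates = (control,) + arms
                if any(not 0.0 < r < 1.0 for r in rates):
                    raise ValueError("binary outcomes require event rates strictly in (0, 1)")
            if outcome == TTE and self.dialect == "subgroup":
                if control <= 0 or any(hr <= 0 for hr in arms):
                    raise ValueError("hazard-ratio dialect requires positive hazards")

    def _default_control(self, outcome, control):
        if control is not None:
            return float(control)
        if outcome == BINARY:
            raise ValueError("binary outcomes require an explicit control event rate")
        if outcome == TTE and self.dialect == "subgroup":
            return 1.0  # baseline hazard
        return 0.0

    @property
    def n_arms(self) -> int:
        return len(self.arm_effects_early)


@dataclass(frozen=True)
class SampleSizePlan:
    """Per-arm sample sizes and population structure.

    ``n1``/``n2`` are patients per arm in stages 1 and 2.  ``enrich``
    (subgroup designs) is the per-arm stage-2 sample size when the trial
    continues in the subgroup only; without it the subgroup carries
    ``n2 * prevalence`` patients per arm.  ``allocation`` is the
    control:experimental randomization ratio lambda (1 = equal).
    """

    n1: float
    n2: float
    enrich: float | None = None
    allocation: float = 1.0
    prevalence: float | None = None
    prevalence_fixed: bool = True

    def __post_init__(self):
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("stage sample sizes must be >= 1")
        if self.enrich is not None and self.enrich < 1:
            raise ValueError("enrichment sample size must be >= 1")
        if self.allocation <= 0:
            raise ValueError("allocation ratio must be positive")
        if self.prevalence is not None and not 0.0 < self.prevalence < 1.0:
            raise ValueError("subgroup prevalence must lie strictly between 0 and 1")


@dataclass(frozen=True)
class CovarianceModel:
    """Mean and covariance of all stage-wise statistics (natural scale)."""

    labels: tuple
    mean: np.ndarray
    cov: np.ndarray
    info: np.ndarray
    design: str
    meta: dict = field(default_factory=dict)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    @property
    def n_slots(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class StageStatistics:
    """Realized statistics for one or more simulated replicates."""

    labels: tuple
    values: np.ndarray  # (..., n_slots)

    def slot(self, label: str) -> np.ndarray:
        return self.values[..., self.labels.index(label)]


# ---------------------------------------------------------------------------
# model builders
# ---------------------------------------------------------------------------


def _check_psd(cov: np.ndarray) -> None:
    if np.min(np.linalg.eigvalsh(cov)) < -_PSD_TOL:
        raise ValueError("covariance matrix is not positive semi-definite "
                         "(inconsistent correlation/allocation parameters)")


def build_model_treatsel(effects: EffectSpec, plan: SampleSizePlan) -> CovarianceModel:
    """Joint distribution of statistics for a K-arm treatment-selection design.

    Slots are ordered ``E_1..E_K`` (early outcome, stage 1),
    ``F1_1..F1_K`` (final outcome, stage-1 patients) and ``F2_1..F2_K``
    (final outcome, stage-2 increment on n2 fresh patients per arm).
    The covariance is the Kronecker product of the endpoint/stage factor
    ``[[1, rho, 0], [rho, 1, 0], [0, 0, 1]]`` with the compound-symmetric
    between-arm factor with off-diagonal ``1/(1+lambda)`` — exactly the
    covariance induced by shared control patients and within-patient
    endpoint correlation ``rho``.
    """
    if effects.dialect != "treatment":
        raise ValueError("treatment-selection model requires treatment-dialect effects")
    K = effects.n_arms
    rho = effects.corr
    r = 1.0 / (1.0 + plan.allocation)

    mu_e, info_e = effect_statistic(
        effects.outcome_early, "treatment", plan.n1, effects.control_early,
        np.asarray(effects.arm_effects_early))
    mu_f1, info_f1 = effect_statistic(
        effects.outcome_final, "treatment", plan.n1, effects.control_final,
        np.asarray(effects.arm_effects_final))
    mu_f2, info_f2 = effect_statistic(
        effects.outcome_final, "treatment", plan.n2, effects.control_final,
        np.asarray(effects.arm_effects_final))

    endpoint = np.array([[1.0, rho, 0.0], [rho, 1.0, 0.0], [0.0, 0.0, 1.0]])
    between = np.full((K, K), r)
    np.fill_diagonal(between, 1.0)
    cov = np.kron(endpoint, between)
    _check_psd(cov)

    labels = tuple(
        f"{block}_{k + 1}" for block in ("E", "F1", "F2") for k in range(K)
    )
    mean = np.concatenate([mu_e, mu_f1, mu_f2])
    info = np.concatenate([
        np.broadcast_to(info_e, (K,)),
        np.broadcast_to(info_f1, (K,)),
        np.broadcast_to(info_f2, (K,)),
    ])
    return CovarianceModel(
        labels=labels, mean=mean, cov=cov, info=info, design="treatment",
        meta={"n_arms": K, "between_arm_corr": r},
    )


_CONTINUATIONS = ("both", "subgroup-only", "full-only")


def build_model_subpop(effects: EffectSpec, plan: SampleSizePlan,
                       continuation: str = "both") -> CovarianceModel:
    """Joint distribution of statistics for a subgroup-selection design.

    Slots are ``E_S, E_F, F1_S, F1_F, F2_S, F2_F`` (subgroup / full
    population per block).  Within a block, the subgroup--full
    correlation is ``sqrt(I_S / I_F)``, the group-sequential correlation
    induced by nesting.  ``continuation`` controls the stage-2 subgroup
    information: ``n2 * tau`` under ``"both"``, the enrichment sample
    size (or ``n2 * tau`` when no enrichment is planned) under
    ``"subgroup-only"``.
    """
    if effects.dialect != "subgroup":
        raise ValueError("subgroup model requires subgroup-dialect effects")
    if effects.n_arms != 2:
        raise ValueError("subgroup designs carry exactly (subgroup, full) effect pairs")
    if plan.prevalence is None:
        raise ValueError("subgroup designs require a prevalence")
    if continuation not in _CONTINUATIONS:
        raise ValueError(f"unknown continuation: {continuation!r}")

    tau = plan.prevalence
    rho = effects.corr
    eff_e = effects.arm_effects_early
    eff_f = effects.arm_effects_final

    n1_s, n1_f = plan.n1 * tau, plan.n1
    if continuation == "subgroup-only":
        n2_s = plan.enrich if plan.enrich is not None else plan.n2 * tau
    else:
        n2_s = plan.n2 * tau
    n2_f = plan.n2

    mu = np.empty(6)
    info = np.empty(6)
    slots = (
        (effects.outcome_early, n1_s, effects.control_early, eff_e[0]),
        (effects.outcome_early, n1_f, effects.control_early, eff_e[1]),
        (effects.outcome_final, n1_s, effects.control_final, eff_f[0]),
        (effects.outcome_final, n1_f, effects.control_final, eff_f[1]),
        (effects.outcome_final, n2_s, effects.control_final, eff_f[0]),
        (effects.outcome_final, n2_f, effects.control_final, eff_f[1]),
    )
    for i, (outcome, n, control, eff) in enumerate(slots):
        mu[i], info[i] = effect_statistic(outcome, "subgroup", n, control, eff)

    a_e = np.sqrt(min(info[0] / info[1], 1.0))
    a_f1 = np.sqrt(min(info[2] / info[3], 1.0))
    a_f2 = np.sqrt(min(info[4] / info[5], 1.0))
    for ratio, name in ((info[0] / info[1], "early"), (info[2] / info[3], "final stage 1")):
        if ratio > 1.0 + 1e-9:
            raise ValueError(f"subgroup information exceeds full-population information ({name})")
    b_e = np.sqrt(1.0 - a_e ** 2)
    b_f1 = np.sqrt(1.0 - a_f1 ** 2)

    cov = np.eye(6)
    cov[0, 1] = cov[1, 0] = a_e
    cov[2, 3] = cov[3, 2] = a_f1
    cov[4, 5] = cov[5, 4] = a_f2
    # cross-endpoint entries from the constructive decomposition
    # F-pop statistic = a * subgroup part + b * complement part
    cov[0, 2] = cov[2, 0] = rho
    cov[1, 3] = cov[3, 1] = rho * (a_e * a_f1 + b_e * b_f1)
    cov[0, 3] = cov[3, 0] = rho * a_f1
    cov[1, 2] = cov[2, 1] = rho * a_e
    _check_psd(cov)

    labels = ("E_S", "E_F", "F1_S", "F1_F", "F2_S", "F2_F")
    return CovarianceModel(
        labels=labels, mean=mu, cov=cov, info=info, design="subgroup",
        meta={"continuation": continuation, "prevalence": tau,
              "pop_corr": {"early": a_e, "final1": a_f1, "final2": a_f2}},
    )


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------


def covariance_factor(cov: np.ndarray) -> np.ndarray:
    """Square root ``L`` of ``cov`` with ``L @ L.T == cov``.

    Cholesky when possible, symmetric eigen factor for the singular
    boundary cases (e.g. ``corr = 1`` or ``tau -> 1``).
    """
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(cov)
        return v * np.sqrt(np.clip(w, 0.0, None))


def draw_statistics(model: CovarianceModel, rng: np.random.Generator,
                    size: int = 1) -> StageStatistics:
    """Draw ``size`` replicates of all statistics from the model.

    Deterministic given the generator state; repeated draws converge to
    the model's mean and covariance.
    """
    _check_psd(model.cov)
    factor = covariance_factor(model.cov)
    z = rng.standard_normal((size, model.n_slots))
    return StageStatistics(labels=model.labels, values=model.mean + z @ factor.T)


def cumulative_statistic(s1, s2, info1, info2):
    """Information-weighted cumulative z from stage-wise statistics.

    ``(sqrt(I1)*S1 + sqrt(I2)*S2) / sqrt(I1 + I2)`` — the statistic that
    would have been observed on the pooled stage-1 + stage-2 data.
    """
    info1 = np.asarray(info1, dtype=float)
    info2 = np.asarray(info2, dtype=float)
    return (np.sqrt(info1) * s1 + np.sqrt(info2) * s2) / np.sqrt(info1 + info2)
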