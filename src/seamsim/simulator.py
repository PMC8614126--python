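"""Monte Carlo drivers for treatment-selection and subgroup-selection designs.

Each replicate draws the stage-1 early and final statistics from the
joint normal model, applies the interim selection rule to the early
statistics, draws independent stage-2 increments for the continuing
arms or population branch, and runs the closed combination test.
Operating characteristics (selection frequencies, per-hypothesis
rejection rates, futility rate, expected total sample size) are
accumulated over ``nsim`` replicates.

Randomness is organized as independent substreams spawned from one root
seed (statistic draws / tie-breaks / prevalence draws), so results are
reproducible given the seed and adding a rule does not perturb the
other streams.  Runtime is linear in ``nsim`` and independent of the
patient-level sample sizes because only population statistics are
simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .inference import (
    CombinationWeights,
    closed_test_subpop,
    closed_test_treatsel,
)
from .model import (
    EffectSpec,
    SampleSizePlan,
    build_model_subpop,
    build_model_treatsel,
    canonical_sign,
    covariance_factor,
    effect_statistic,
)
from .selection import (
    SUBGROUP_RULES,
    TREATMENT_RULES,
    Continuation,
    SelectionRule,
    select_populations_futility,
    select_populations_threshold,
    select_treatments,
)

__all__ = [
    "DesignSpec",
    "SimulationSummary",
    "simulate",
    "simulate_treatsel",
    "simulate_subpop",
    "expected_sample_size",
    "MAX_ARMS",
    "MAX_NSIM",
]

MAX_ARMS = 7
MAX_NSIM = int(1e7)

_TREATMENT_METHODS = ("invnorm", "fisher")
_SUBGROUP_METHODS = ("CT-SD", "CT-Simes", "CT-Bonferroni")


@dataclass(frozen=True)
class DesignSpec:
    """Complete configuration of a two-stage seamless design."""

    design: str  # "treatment" | "subgroup"
    effects: EffectSpec
    plan: SampleSizePlan
    rule: SelectionRule
    method: str = "invnorm"
    weights: CombinationWeights | None = None
    alpha: float = 0.025
    nsim: int = 1000
    seed: int | None = None
    followup: str = "discontinued"
    ptest: tuple = ()  # 1-based arm indices for the combined rejection count

    def __post_init__(self):
        if self.design not in ("treatment", "subgroup"):
            raise ValueError(f"unknown design: {self.design!r}")
        if not 1 <= self.nsim <= MAX_NSIM:
            raise ValueError(f"nsim must lie in [1, {MAX_NSIM}]")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("test level must lie strictly between 0 and 1")
        if self.followup not in ("discontinued", "complete"):
            raise ValueError(f"unknown follow-up mode: {self.followup!r}")
        k = self.effects.n_arms
        if self.design == "treatment":
            if self.effects.dialect != "treatment":
                raise ValueError("treatment designs require treatment-dialect effects")
            if self.method not in _TREATMENT_METHODS:
                raise ValueError(
                    f"method {self.method!r} is not valid for treatment selection")
            if self.rule.kind not in TREATMENT_RULES:
                raise ValueError(
                    f"rule {self.rule.kind!r} is not a treatment-selection rule")
            if k > MAX_ARMS:
                raise ValueError(f"at most {MAX_ARMS} experimental arms are supported")
            ptest = tuple(int(p) for p in self.ptest) or tuple(range(1, k + 1))
            if not set(ptest) <= set(range(1, k + 1)):
                raise ValueError("ptest must contain valid 1-based arm numbers")
            object.__setattr__(self, "ptest", ptest)
        else:
            if self.effects.dialect != "subgroup":
                raise ValueError("subgroup designs require subgroup-dialect effects")
            if self.method not in _SUBGROUP_METHODS:
                raise ValueError(
                    f"method {self.method!r} is not valid for subgroup selection")
            if self.rule.kind not in SUBGROUP_RULES:
                raise ValueError(
                    f"rule {self.rule.kind!r} is not a subgroup-selection rule")
            if self.rule.selim is None:
                raise ValueError("subgroup selection rules require selim limits")
            if self.plan.prevalence is None:
                raise ValueError("subgroup designs require a prevalence")
            object.__setattr__(self, "ptest", (1, 2))

    def resolved_weights(self) -> CombinationWeights:
        """Pre-specified weights; by default squared weights n1/(n1+n2), n2/(n1+n2)."""
        if self.weights is not None:
            return self.weights
        return CombinationWeights.from_sample_sizes(self.plan.n1, self.plan.n2)


@dataclass
class SimulationSummary:
    """Accumulated operating characteristics of one simulated design."""

    design: str
    nsim: int
    expectations: dict
    weights: tuple
    futility: int
    continuing: int
    expected_sample_size_: float
    # treatment-selection fields
    n_selected: list | None = None        # counts of replicates selecting m = 1..K arms
    per_arm_selection: list | None = None
    rejections: list | None = None
    ptest: tuple | None = None
    ptest_rejections: int | None = None
    # subgroup-selection fields
    branch_counts: dict | None = None     # sub / full / both / futility
    table: dict | None = None             # per branch: Hs, Hf, Hs+Hf, Hs|f counts
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        """JSON-safe plain-type view (lossless for all summary fields)."""
        out = {
            "design": self.design,
            "nsim": int(self.nsim),
            "expectations": {k: (list(np.round(np.atleast_1d(v).astype(float), 10)))
                             for k, v in self.expectations.items()},
            "weights": [float(w) for w in self.weights],
            "futility": int(self.futility),
            "continuing": int(self.continuing),
            "expected_sample_size": float(self.expected_sample_size_),
        }
        if self.design == "treatment":
            out.update({
                "n_selected": [int(c) for c in self.n_selected],
                "per_arm_selection": [int(c) for c in self.per_arm_selection],
                "rejections": [int(c) for c in self.rejections],
                "ptest": [int(p) for p in self.ptest],
                "ptest_rejections": int(self.ptest_rejections),
            })
        else:
            out.update({
                "branch_counts": {k: int(v) for k, v in self.branch_counts.items()},
                "table": {row: {k: int(v) for k, v in rec.items()}
                          for row, rec in self.table.items()},
            })
        return out


def _spawn_rngs(seed, n):
    children = np.random.SeedSequence(seed).spawn(n)
    return [np.random.default_rng(s) for s in children]


def simulate(spec: DesignSpec) -> SimulationSummary:
    """Dispatch to the treatment- or subgroup-selection driver."""
    if spec.design == "treatment":
        return simulate_treatsel(spec)
    return simulate_subpop(spec)


# ---------------------------------------------------------------------------
# treatment selection
# ---------------------------------------------------------------------------


def simulate_treatsel(spec: DesignSpec) -> SimulationSummary:
    """Monte Carlo operating characteristics of a treatment-selection design.

    Per replicate: draw the early and final stage-1 statistics and the
    stage-2 increments jointly, select arms on the early statistics,
    and run the closed Dunnett combination test.  Under complete
    follow-up, dropped arms contribute a stage-2 statistic at stage-1
    information (their stage-1 patients followed to the final outcome);
    under discontinued follow-up they contribute nothing.
    """
    if spec.design != "treatment":
        raise ValueError("simulate_treatsel requires a treatment-selection design")
    k = spec.effects.n_arms
    nsim = spec.nsim
    plan = spec.plan
    model = build_model_treatsel(spec.effects, plan)
    weights = spec.resolved_weights()
    rng_draw, rng_tie = _spawn_rngs(spec.seed, 2)

    factor = covariance_factor(model.cov)
    residuals = rng_draw.standard_normal((nsim, 3 * k)) @ factor.T
    mu_e, mu_f1, mu_f2 = model.mean[:k], model.mean[k:2 * k], model.mean[2 * k:]

    z_early = mu_e + residuals[:, :k]
    z_final1 = mu_f1 + residuals[:, k:2 * k]
    selected = select_treatments(z_early, spec.rule, rng_tie)
    # dropped arms under complete follow-up carry stage-1 information
    mu_stage2 = np.where(selected, mu_f2, mu_f1 if spec.followup == "complete" else mu_f2)
    z_final2 = mu_stage2 + residuals[:, 2 * k:]

    elementary, _ = closed_test_treatsel(
        z_final1, z_final2, selected, weights=weights, alpha=spec.alpha,
        allocation=plan.allocation, method=spec.method, followup=spec.followup)

    m = selected.sum(axis=1)
    futility = int((m == 0).sum())
    n_selected = [int((m == i).sum()) for i in range(1, k + 1)]
    per_arm = selected.sum(axis=0)
    rejections = elementary.sum(axis=0)
    ptest_idx = [p - 1 for p in spec.ptest]
    ptest_rej = int(elementary[:, ptest_idx].any(axis=1).sum())
    esize = float(((k + 1) * plan.n1 + np.where(m >= 1, (m + 1) * plan.n2, 0.0)).mean())

    expectations = {
        "early": mu_e,
        "final_stage1": mu_f1,
        "final_stage2": mu_f2,
    }
    return SimulationSummary(
        design="treatment", nsim=nsim, expectations=expectations,
        weights=(weights.w1, weights.w2), futility=futility,
        continuing=nsim - futility, expected_sample_size_=esize,
        n_selected=n_selected, per_arm_selection=[int(c) for c in per_arm],
        rejections=[int(c) for c in rejections], ptest=spec.ptest,
        ptest_rejections=ptest_rej,
        meta={"method": spec.method, "alpha": spec.alpha,
              "followup": spec.followup},
    )


# ---------------------------------------------------------------------------
# subgroup selection
# ---------------------------------------------------------------------------


def _subpop_slots(effects: EffectSpec, n_sub, n_full, which: str):
    """Vectorized (mean, info) for the subgroup and full-population slots."""
    outcome = effects.outcome_early if which == "early" else effects.outcome_final
    control = effects.control_early if which == "early" else effects.control_final
    arm = effects.arm_effects_early if which == "early" else effects.arm_effects_final
    mu_s, info_s = effect_statistic(outcome, "subgroup", n_sub, control, arm[0])
    mu_f, info_f = effect_statistic(outcome, "subgroup", n_full, control, arm[1])
    return mu_s, info_s, mu_f, info_f


def simulate_subpop(spec: DesignSpec) -> SimulationSummary:
    """Monte Carlo operating characteristics of a subgroup-selection design.

    The full-population residual is built from the subgroup part plus an
    independent complement part (weight ``sqrt(I_S/I_F)``), which keeps
    the covariance consistent replicate-by-replicate when the realized
    prevalence varies.  Selection uses the early statistics (natural
    scale for the futility rule, canonical for the threshold rule); the
    branch taken fixes the stage-2 information of the subgroup slot
    (enrichment under subgroup-only continuation).
    """
    if spec.design != "subgroup":
        raise ValueError("simulate_subpop requires a subgroup-selection design")
    nsim = spec.nsim
    plan = spec.plan
    effects = spec.effects
    weights = spec.resolved_weights()
    rho = effects.corr
    rng_draw, rng_tie, rng_prev = _spawn_rngs(spec.seed, 3)

    if plan.prevalence_fixed:
        tau = np.full(nsim, plan.prevalence)
    else:
        total1 = int(round(2 * plan.n1))  # planned stage-1 total over both arms
        draws = rng_prev.binomial(total1, plan.prevalence, size=nsim)
        tau = np.clip(draws / total1, 1.0 / total1, 1.0 - 1.0 / total1)

    mu_e_s, info_e_s, mu_e_f, info_e_f = _subpop_slots(effects, plan.n1 * tau, plan.n1, "early")
    mu_f1_s, info_f1_s, mu_f1_f, info_f1_f = _subpop_slots(effects, plan.n1 * tau, plan.n1, "final")
    n2_sub_both = plan.n2 * tau
    n2_sub_only = (np.full(nsim, float(plan.enrich)) if plan.enrich is not None
                   else plan.n2 * tau)
    mu_f2_s_both, info_f2_s_both, mu_f2_f, info_f2_f = _subpop_slots(
        effects, n2_sub_both, plan.n2, "final")
    mu_f2_s_only, _, _, _ = _subpop_slots(effects, n2_sub_only, plan.n2, "final")

    a_e = np.sqrt(np.minimum(info_e_s / info_e_f, 1.0))
    a_f1 = np.sqrt(np.minimum(info_f1_s / info_f1_f, 1.0))
    a_f2 = np.sqrt(np.minimum(info_f2_s_both / info_f2_f, 1.0))

    x = rng_draw.standard_normal((nsim, 6))
    rho_c = np.sqrt(1.0 - rho ** 2)
    e_part_s, f_part_s = x[:, 0], rho * x[:, 0] + rho_c * x[:, 1]
    e_part_c, f_part_c = x[:, 2], rho * x[:, 2] + rho_c * x[:, 3]
    z_e_s = mu_e_s + e_part_s
    z_e_f = mu_e_f + a_e * e_part_s + np.sqrt(1.0 - a_e ** 2) * e_part_c
    z_f1_s = mu_f1_s + f_part_s
    z_f1_f = mu_f1_f + a_f1 * f_part_s + np.sqrt(1.0 - a_f1 ** 2) * f_part_c

    sign_e = canonical_sign(effects.outcome_early, "subgroup")
    if spec.rule.kind == "futility":
        branch = select_populations_futility(z_e_s, z_e_f, spec.rule.selim)
    else:
        branch = select_populations_threshold(sign_e * z_e_s, sign_e * z_e_f,
                                              spec.rule.selim)
    sub_tested = (branch == Continuation.BOTH) | (branch == Continuation.SUBGROUP_ONLY)
    full_tested = (branch == Continuation.BOTH) | (branch == Continuation.FULL_ONLY)

    mu_f2_s = np.where(branch == Continuation.SUBGROUP_ONLY, mu_f2_s_only, mu_f2_s_both)
    z_f2_s = mu_f2_s + x[:, 4]
    z_f2_f = mu_f2_f + a_f2 * x[:, 4] + np.sqrt(1.0 - a_f2 ** 2) * x[:, 5]

    sign_f = canonical_sign(effects.outcome_final, "subgroup")
    reject_sub, reject_full, _ = closed_test_subpop(
        sign_f * z_f1_s, sign_f * z_f1_f, sign_f * z_f2_s, sign_f * z_f2_f,
        sub_tested, full_tested,
        info_f1_s / info_f1_f, info_f2_s_both / info_f2_f,
        method=spec.method, weights=weights, alpha=spec.alpha)

    rows = (("sub", Continuation.SUBGROUP_ONLY), ("full", Continuation.FULL_ONLY),
            ("both", Continuation.BOTH))
    table = {}
    for name, code in rows:
        mask = branch == code
        table[name] = {
            "Hs": int((reject_sub & mask).sum()),
            "Hf": int((reject_full & mask).sum()),
            "Hs+Hf": int((reject_sub & reject_full & mask).sum()),
            "Hs|f": int(((reject_sub | reject_full) & mask).sum()),
            "n": int(mask.sum()),
        }
    futility = int((branch == Continuation.FUTILITY).sum())
    branch_counts = {name: table[name]["n"] for name, _ in rows}
    branch_counts["futility"] = futility

    stage2_n = np.where(
        branch == Continuation.FUTILITY, 0.0,
        np.where(branch == Continuation.SUBGROUP_ONLY, 2.0 * n2_sub_only, 2.0 * plan.n2))
    esize = float((2.0 * plan.n1 + stage2_n).mean())

    # deterministic model headers at the planned prevalence
    model_both = build_model_subpop(effects, plan, "both")
    model_sub = build_model_subpop(effects, plan, "subgroup-only")
    model_full = build_model_subpop(effects, plan, "full-only")
    expectations = {
        "early": model_both.mean[:2],
        "final_stage1": model_both.mean[2:4],
        "final_stage2_only": np.array([model_sub.mean[4], model_full.mean[5]]),
        "final_stage2_both": model_both.mean[4:],
    }
    return SimulationSummary(
        design="subgroup", nsim=nsim, expectations=expectations,
        weights=(weights.w1, weights.w2), futility=futility,
        continuing=nsim - futility, expected_sample_size_=esize,
        branch_counts=branch_counts, table=table,
        meta={"method": spec.method, "alpha": spec.alpha,
              "prevalence": plan.prevalence,
              "prevalence_fixed": plan.prevalence_fixed},
    )


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


def expected_sample_size(summary: SimulationSummary, plan: SampleSizePlan,
                         n_arms: int | None = None) -> float:
    """Expected total sample size recomputed from the selection counts.

    Treatment designs: ``(K+1)*n1 + E[(m+1)*n2 ; m >= 1]`` with ``m``
    the number of arms selected (futility stops contribute stage 1
    only).  Subgroup designs: ``2*n1`` plus ``2*n2`` per continuing
    replicate in the full population or both, and ``2*enrich`` (or
    ``2*n2*prevalence``) for subgroup-only continuation.
    """
    if summary.design == "treatment":
        if n_arms is None:
            n_arms = len(summary.per_arm_selection)
        stage2 = sum(count * (m + 1) * plan.n2
                     for m, count in enumerate(summary.n_selected, start=1))
        return (n_arms + 1) * plan.n1 + stage2 / summary.nsim
    n_sub = plan.enrich if plan.enrich is not None else plan.n2 * plan.prevalence
    stage2 = (2.0 * plan.n2 * (summary.branch_counts["both"] + summary.branch_counts["full"])
              + 2.0 * n_sub * summary.branch_counts["sub"])
    return 2.0 * plan.n1 + stage2 / summary.nsim
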