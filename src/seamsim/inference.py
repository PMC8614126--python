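"""Combination tests, intersection p-values and the closed testing procedure.

Stage-wise p-values are combined with the inverse-normal rule
``C_K = w1 * Phi^-1(1 - p_K1) + w2 * Phi^-1(1 - p_K2)`` (or Fisher's
product criterion), and every intersection hypothesis ``H_K`` is tested
at level alpha; an elementary hypothesis is rejected only if every
intersection containing it is rejected (closed testing), which controls
the familywise error rate in the strong sense for any data-driven
selection.

Intersection p-values: Dunnett's many-to-one test for treatment
selection (between-arm correlation ``1/(1+lambda)``), and the
Spiessens-Debois, Simes or Bonferroni tests for the subgroup / full
population pair.  After the interim, the stage-2 p-value for ``H_K`` is
the p-value of ``H_(K ∩ selected)``: hypotheses that were dropped no
longer contribute stage-2 evidence and can never be rejected.

Both needed multivariate-normal structures are equicorrelated, so tail
probabilities are computed by deterministic Gauss-Hermite quadrature of
``P(max_i Z_i <= z) = E_W[ Phi((z - sqrt(r) W)/sqrt(1-r))^m ]``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy.special import ndtr, ndtri
from scipy.stats import chi2

__all__ = [
    "CombinationWeights",
    "ClosedTestResult",
    "inverse_normal_combine",
    "fisher_critical_value",
    "fisher_combine",
    "equicorrelated_max_cdf",
    "dunnett_pvalue",
    "simes_pvalue",
    "bonferroni_pvalue",
    "spiessens_debois_pvalue",
    "closed_test",
    "closed_test_treatsel",
    "closed_test_subpop",
]

#: cap on normal quantiles so that p in {0, 1} (including the "-inf for
#: dropped arms" convention) stays finite; changes no decision at any
#: alpha >= 1e-15.
QNORM_CAP = 8.2

_GH_X, _GH_W = np.polynomial.hermite.hermgauss(96)
_GH_W = _GH_W / np.sqrt(np.pi)


def _phi_inv_upper(p):
    """Capped upper-tail normal quantile ``Phi^-1(1 - p)``."""
    with np.errstate(divide="ignore", invalid="ignore"):
        q = ndtri(1.0 - np.asarray(p, dtype=float))
    return np.clip(q, -QNORM_CAP, QNORM_CAP)


# ---------------------------------------------------------------------------
# combination functions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CombinationWeights:
    """Pre-specified inverse-normal stage weights with w1^2 + w2^2 = 1."""

    w1: float
    w2: float

    def __post_init__(self):
        if self.w1 < 0 or self.w2 < 0:
            raise ValueError("combination weights must be non-negative")
        if abs(self.w1 ** 2 + self.w2 ** 2 - 1.0) > 1e-9:
            raise ValueError("squared combination weights must sum to 1")

    @classmethod
    def from_sample_sizes(cls, n1: float, n2: float) -> "CombinationWeights":
        """Default weights with squared weights n1/(n1+n2) and n2/(n1+n2)."""
        total = float(n1) + float(n2)
        return cls(np.sqrt(n1 / total), np.sqrt(n2 / total))


def inverse_normal_combine(p1, p2, weights: CombinationWeights):
    """Combined z and p for two stage-wise p-values.

    Returns ``(z, p)`` with ``z = w1*Phi^-1(1-p1) + w2*Phi^-1(1-p2)``
    and ``p = 1 - Phi(z)``; decreasing in each input p-value.
    """
    z = weights.w1 * _phi_inv_upper(p1) + weights.w2 * _phi_inv_upper(p2)
    return z, ndtr(-z)


def fisher_critical_value(alpha: float) -> float:
    """Critical value c with ``reject iff p1*p2 <= c`` for Fisher's product test.

    ``c = exp(-q/2)`` with q the upper-alpha chi-square(4 df) quantile;
    equivalently the solution of ``c * (1 - log c) = alpha``.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie strictly between 0 and 1")
    return float(np.exp(-0.5 * chi2.isf(alpha, df=4)))


def fisher_combine(p1, p2, alpha: float):
    """Fisher product-test decision; returns ``(reject, critical value)``."""
    c = fisher_critical_value(alpha)
    return np.asarray(p1, float) * np.asarray(p2, float) <= c, c


# ---------------------------------------------------------------------------
# intersection p-values
# ---------------------------------------------------------------------------


def equicorrelated_max_cdf(z, m: int, rho):
    """``P(max(Z_1..Z_m) <= z)`` for standard normals with common correlation rho.

    Deterministic 96-node Gauss-Hermite quadrature (absolute accuracy far
    below 1e-6 for m <= 8); ``rho = 1`` degenerates to ``Phi(z)``.
    """
    z = np.asarray(z, dtype=float)
    rho = np.asarray(rho, dtype=float)
    if np.any(rho < 0.0) or np.any(rho > 1.0):
        raise ValueError("common correlation must lie in [0, 1]")
    m = int(m)
    if m < 1:
        raise ValueError("at least one statistic is required")
    z_b, rho_b = np.broadcast_arrays(z, rho)
    near_one = rho_b > 1.0 - 1e-12
    rho_safe = np.where(near_one, 0.5, rho_b)
    t = (z_b[..., None] - np.sqrt(2.0 * rho_safe[..., None]) * _GH_X) / np.sqrt(1.0 - rho_safe[..., None])
    out = ndtr(t) ** m @ _GH_W
    out = np.where(near_one, ndtr(z_b), out)
    return np.clip(out, 0.0, 1.0)


def dunnett_pvalue(z_values, allocation: float = 1.0) -> float:
    """Dunnett many-to-one p-value ``1 - P(all Z_i <= max z)``.

    The m comparison statistics against the shared control are
    equicorrelated with ``1/(1+lambda)``; reduces to ``1 - Phi(z)`` for
    a single arm.
    """
    z = np.atleast_1d(np.asarray(z_values, dtype=float))
    if z.size == 0:
        raise ValueError("empty hypothesis set")
    if allocation <= 0:
        raise ValueError("allocation ratio must be positive")
    r = 1.0 / (1.0 + allocation)
    return float(1.0 - equicorrelated_max_cdf(z.max(), z.size, r))


def simes_pvalue(p_values) -> float:
    """Simes intersection p-value ``min_j m * p_(j) / j``."""
    p = np.sort(np.atleast_1d(np.asarray(p_values, dtype=float)))
    if p.size == 0:
        raise ValueError("empty hypothesis set")
    return float(np.min(p.size * p / np.arange(1, p.size + 1)))


def bonferroni_pvalue(p_values) -> float:
    """Bonferroni intersection p-value ``min(1, m * min p)``."""
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    if p.size == 0:
        raise ValueError("empty hypothesis set")
    return float(min(1.0, p.size * p.min()))


def spiessens_debois_pvalue(z_subgroup, z_full, info_ratio) -> float:
    """Spiessens-Debois p-value for the subgroup/full-population intersection.

    A Dunnett-type test where the two statistics are correlated with
    ``sqrt(I_S / I_F)`` because the subgroup is nested in the full
    population; ``info_ratio = 1`` collapses to ``1 - Phi(max z)`` and
    ``info_ratio -> 0`` to the independent pair ``1 - Phi(max z)^2``.
    """
    info_ratio = float(info_ratio)
    if not 0.0 < info_ratio <= 1.0:
        raise ValueError("information ratio must lie in (0, 1]")
    zmax = max(float(z_subgroup), float(z_full))
    return float(1.0 - equicorrelated_max_cdf(zmax, 2, np.sqrt(info_ratio)))


# ---------------------------------------------------------------------------
# closed testing procedure
# ---------------------------------------------------------------------------


def _subset_members(mask: int, k: int):
    return [i for i in range(k) if mask >> i & 1]


def _pair_intersection_p(z_s, z_f, p_s, p_f, rho, method: str):
    """Vectorized subgroup/full intersection p-value for one test family."""
    if method == "CT-SD":
        zmax = np.maximum(z_s, z_f)
        return 1.0 - equicorrelated_max_cdf(zmax, 2, rho)
    lo = np.minimum(p_s, p_f)
    hi = np.maximum(p_s, p_f)
    if method == "CT-Simes":
        return np.minimum(2.0 * lo, hi)
    if method == "CT-Bonferroni":
        return np.minimum(1.0, 2.0 * lo)
    raise ValueError(f"unknown subgroup method: {method!r}")


def closed_test_treatsel(z1, z2, selected, *, weights: CombinationWeights,
                         alpha: float = 0.025, allocation: float = 1.0,
                         method: str = "invnorm",
                         followup: str = "discontinued"):
    """Closed Dunnett combination test, vectorized over replicates.

    ``z1``/``z2`` are (B, K) canonical (larger = better) stage-wise
    statistics, ``selected`` the (B, K) boolean interim selection.  For
    each intersection K, the stage-1 p-value is the Dunnett p over all
    of K; the stage-2 p-value is the Dunnett p over ``K ∩ selected``
    (1 when empty) under discontinued follow-up, or over all of K when
    dropped arms were followed up to the final outcome.  Returns
    ``(elementary, intersections)``: a (B, K) boolean rejection matrix
    (dropped hypotheses are never rejected) and a dict keyed by subset
    bitmask with per-replicate records.
    """
    z1 = np.atleast_2d(np.asarray(z1, dtype=float))
    z2 = np.atleast_2d(np.asarray(z2, dtype=float))
    selected = np.atleast_2d(np.asarray(selected, dtype=bool))
    n_rep, k = z1.shape
    if z2.shape != z1.shape or selected.shape != z1.shape:
        raise ValueError("stage statistics and selection must share one shape")
    if method not in ("invnorm", "fisher"):
        raise ValueError(f"unknown combination method: {method!r}")
    if followup not in ("discontinued", "complete"):
        raise ValueError(f"unknown follow-up mode: {followup!r}")
    r = 1.0 / (1.0 + allocation)
    z_crit = ndtri(1.0 - alpha)
    c_alpha = fisher_critical_value(alpha) if method == "fisher" else None

    intersections = {}
    for mask in range(1, 1 << k):
        idx = _subset_members(mask, k)
        m1 = len(idx)
        p1 = 1.0 - equicorrelated_max_cdf(z1[:, idx].max(axis=1), m1, r)
        if followup == "complete":
            p2 = 1.0 - equicorrelated_max_cdf(z2[:, idx].max(axis=1), m1, r)
        else:
            sel_k = selected[:, idx]
            m2 = sel_k.sum(axis=1)
            z2_max = np.where(sel_k, z2[:, idx], -np.inf).max(axis=1)
            p2 = np.ones(n_rep)
            for m in np.unique(m2):
                if m == 0:
                    continue
                grp = m2 == m
                p2[grp] = 1.0 - equicorrelated_max_cdf(z2_max[grp], int(m), r)
        if method == "invnorm":
            stat, _ = inverse_normal_combine(p1, p2, weights)
            reject = stat >= z_crit
        else:
            reject = p1 * p2 <= c_alpha
            stat = p1 * p2
        intersections[mask] = {"p1": p1, "p2": p2, "stat": stat, "reject": reject}

    elementary = selected.copy()
    for mask, rec in intersections.items():
        for arm in _subset_members(mask, k):
            elementary[:, arm] &= rec["reject"]
    return elementary, intersections


def closed_test_subpop(z1_s, z1_f, z2_s, z2_f, sub_tested, full_tested,
                       info_ratio_stage1, info_ratio_stage2, *,
                       method: str = "CT-SD", weights: CombinationWeights,
                       alpha: float = 0.025):
    """Closed combination test for the subgroup / full-population pair.

    Statistics are canonical (larger = better) per-replicate arrays;
    ``sub_tested`` / ``full_tested`` are the boolean continuation masks
    from the interim rule (both False = futility stop).  Info ratios are
    ``I_S / I_F`` for the stage-1 and stage-2 final-outcome statistics
    (scalar or per replicate) and drive the Spiessens-Debois
    correlation.  Returns ``(reject_sub, reject_full, intersections)``.
    """
    z1_s, z1_f, z2_s, z2_f = (np.atleast_1d(np.asarray(a, dtype=float))
                              for a in (z1_s, z1_f, z2_s, z2_f))
    sub_tested = np.atleast_1d(np.asarray(sub_tested, dtype=bool))
    full_tested = np.atleast_1d(np.asarray(full_tested, dtype=bool))
    n_rep = z1_s.shape[0]
    if method not in ("CT-SD", "CT-Simes", "CT-Bonferroni"):
        raise ValueError(f"unknown subgroup method: {method!r}")
    rho1 = np.sqrt(np.broadcast_to(np.asarray(info_ratio_stage1, dtype=float), (n_rep,)))
    rho2 = np.sqrt(np.broadcast_to(np.asarray(info_ratio_stage2, dtype=float), (n_rep,)))
    z_crit = ndtri(1.0 - alpha)

    p1_s = ndtr(-z1_s)
    p1_f = ndtr(-z1_f)
    p1_sf = _pair_intersection_p(z1_s, z1_f, p1_s, p1_f, rho1, method)

    p2_s = np.where(sub_tested, ndtr(-z2_s), 1.0)
    p2_f = np.where(full_tested, ndtr(-z2_f), 1.0)
    both = sub_tested & full_tested
    p2_sf = np.ones(n_rep)
    if np.any(both):
        p2_sf[both] = _pair_intersection_p(
            z2_s[both], z2_f[both], p2_s[both], p2_f[both], rho2[both], method)
    only_s = sub_tested & ~full_tested
    only_f = full_tested & ~sub_tested
    p2_sf[only_s] = p2_s[only_s]
    p2_sf[only_f] = p2_f[only_f]

    c_s, _ = inverse_normal_combine(p1_s, p2_s, weights)
    c_f, _ = inverse_normal_combine(p1_f, p2_f, weights)
    c_sf, _ = inverse_normal_combine(p1_sf, p2_sf, weights)
    rej_sf = c_sf >= z_crit
    reject_sub = sub_tested & (c_s >= z_crit) & rej_sf
    reject_full = full_tested & (c_f >= z_crit) & rej_sf
    intersections = {
        "S": {"p1": p1_s, "p2": p2_s, "stat": c_s, "reject": c_s >= z_crit},
        "F": {"p1": p1_f, "p2": p2_f, "stat": c_f, "reject": c_f >= z_crit},
        "SF": {"p1": p1_sf, "p2": p2_sf, "stat": c_sf, "reject": rej_sf},
    }
    return reject_sub, reject_full, intersections


@dataclass(frozen=True)
class ClosedTestResult:
    """Per-intersection and per-elementary-hypothesis decisions (one trial)."""

    intersections: dict
    rejected: dict
    selected: frozenset


def closed_test(stage1, stage2, selected: Iterable[int], *,
                method: str = "dunnett", weights: CombinationWeights,
                alpha: float = 0.025, followup: str = "discontinued",
                allocation: float = 1.0, info_ratio_stage1=None,
                info_ratio_stage2=None) -> ClosedTestResult:
    """Closed testing procedure for a single trial.

    ``stage1``/``stage2`` are length-K canonical statistic vectors
    (K arms, or the (subgroup, full) pair for methods ``simes``,
    ``bonferroni`` and ``sd``), ``selected`` the 0-based indices carried
    into stage 2.  Coherent by construction: ``H_k`` is rejected iff
    every intersection containing k is rejected at level alpha.
    """
    z1 = np.asarray(stage1, dtype=float)
    z2 = np.asarray(stage2, dtype=float)
    k = z1.shape[-1]
    sel_set = frozenset(int(i) for i in selected)
    if not sel_set <= set(range(k)):
        raise ValueError("selected set must be a subset of hypothesis indices")
    sel_mask = np.zeros(k, dtype=bool)
    sel_mask[list(sel_set)] = True

    if method == "dunnett":
        elem, inter = closed_test_treatsel(
            z1[None, :], z2[None, :], sel_mask[None, :], weights=weights,
            alpha=alpha, allocation=allocation, method="invnorm",
            followup=followup)
        intersections = {
            frozenset(_subset_members(mask, k)): {key: float(rec[key][0]) for key in ("p1", "p2", "stat")}
            | {"reject": bool(rec["reject"][0])}
            for mask, rec in inter.items()
        }
        rejected = {i: bool(elem[0, i]) for i in range(k)}
    elif method in ("simes", "bonferroni", "sd"):
        if k != 2:
            raise ValueError("subgroup methods test exactly the (subgroup, full) pair")
        if method == "sd" and (info_ratio_stage1 is None or info_ratio_stage2 is None):
            raise ValueError("the Spiessens-Debois test requires information ratios")
        name = {"simes": "CT-Simes", "bonferroni": "CT-Bonferroni", "sd": "CT-SD"}[method]
        r1 = info_ratio_stage1 if info_ratio_stage1 is not None else 1.0
        r2 = info_ratio_stage2 if info_ratio_stage2 is not None else 1.0
        rej_s, rej_f, inter = closed_test_subpop(
            z1[0], z1[1], z2[0], z2[1], 0 in sel_set, 1 in sel_set,
            r1, r2, method=name, weights=weights, alpha=alpha)
        key_map = {"S": frozenset({0}), "F": frozenset({1}), "SF": frozenset({0, 1})}
        intersections = {
            key_map[key]: {k2: float(rec[k2][0]) for k2 in ("p1", "p2", "stat")}
            | {"reject": bool(rec["reject"][0])}
            for key, rec in inter.items()
        }
        rejected = {0: bool(rej_s[0]), 1: bool(rej_f[0])}
    else:
        raise ValueError(f"unknown method: {method!r}")
    return ClosedTestResult(intersections=intersections, rejected=rejected,
                            selected=sel_set)
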