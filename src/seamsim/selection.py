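"""Interim selection rules.

Selection maps stage-1 early-outcome statistics to the set of
treatments, or the population branch, carried into stage 2. An empty
selection is a futility stop. Treatment rules operate on the canonical
scale (larger = better); the subgroup futility rule operates on the
natural scale as specified by its inequalities (smaller = better for
time-to-event outcomes), with the driver responsible for any
orientation conversion.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

__all__ = [
    "Continuation",
    "SelectionRule",
    "TREATMENT_RULES",
    "SUBGROUP_RULES",
    "select_treatments",
    "select_populations_threshold",
    "select_populations_futility",
]


class Continuation(IntEnum):
    """Population branch taken into stage 2 of a subgroup design."""

    BOTH = 0
    SUBGROUP_ONLY = 1
    FULL_ONLY = 2
    FUTILITY = 3


TREATMENT_RULES = ("all", "best1", "best2", "best3", "epsilon", "random1", "threshold")
SUBGROUP_RULES = ("threshold", "futility")


@dataclass(frozen=True)
class SelectionRule:
    """An interim selection rule and its parameters.

    ``kind`` is one of :data:`TREATMENT_RULES` for treatment designs or
    :data:`SUBGROUP_RULES` for subgroup designs ("threshold" is valid
    for both).  ``epsilon`` parametrizes the epsilon-rule (select every
    arm within epsilon of the best), ``thresh`` the treatment threshold
    rule, and ``selim = (l1, l2)`` the subgroup limits.
    """

    kind: str
    epsilon: float = 1.0
    thresh: float = 1.0
    selim: tuple | None = None

    def __post_init__(self):
        if self.kind not in set(TREATMENT_RULES) | set(SUBGROUP_RULES):
            raise ValueError(f"unknown selection rule: {self.kind!r}")
        if not np.isfinite(self.epsilon) or self.epsilon < 0:
            raise ValueError("epsilon must be finite and non-negative")
        if self.selim is not None:
            object.__setattr__(self, "selim", (float(self.selim[0]), float(self.selim[1])))


def select_treatments(z_early, rule: SelectionRule, rng: np.random.Generator):
    """Boolean mask of treatments carried into stage 2.

    ``z_early`` is (B, K) or (K,) on the canonical scale.  Rules:
    ``all``; ``best1``/``best2``/``best3`` (the M largest, ties broken
    uniformly at random via ``rng``); ``epsilon`` (all within epsilon of
    the maximum); ``random1`` (one arm uniformly at random);
    ``threshold`` (all at or above ``thresh``, possibly none =
    futility).
    """
    z = np.asarray(z_early, dtype=float)
    squeeze = z.ndim == 1
    z2 = np.atleast_2d(z)
    n_rep, k = z2.shape

    if rule.kind == "all":
        mask = np.ones_like(z2, dtype=bool)
    elif rule.kind in ("best1", "best2", "best3"):
        m = int(rule.kind[-1])
        if m > k:
            raise ValueError(f"cannot select best {m} of {k} treatments")
        tie_break = rng.random(z2.shape)
        order = np.lexsort((tie_break, z2), axis=-1)  # ascending in z
        mask = np.zeros_like(z2, dtype=bool)
        np.put_along_axis(mask, order[:, k - m:], True, axis=-1)
    elif rule.kind == "epsilon":
        mask = z2 >= z2.max(axis=-1, keepdims=True) - rule.epsilon
    elif rule.kind == "random1":
        pick = rng.integers(0, k, size=n_rep)
        mask = np.zeros_like(z2, dtype=bool)
        mask[np.arange(n_rep), pick] = True
    elif rule.kind == "threshold":
        mask = z2 >= rule.thresh
    else:
        raise ValueError(f"rule {rule.kind!r} is not a treatment-selection rule")
    return mask[0] if squeeze else mask


def select_populations_threshold(z_subgroup, z_full, selim):
    """Threshold rule on the difference of canonical statistics.

    ``delta = z_full - z_subgroup``: continue in the subgroup only when
    ``delta <= l1``, in the full population only when ``delta > l2``,
    otherwise in both.  ``selim = (-10, 10)`` (in SD units) always keeps
    both; ``selim = (0, 0)`` keeps the population with the larger
    statistic, the subgroup on ties.
    """
    l1, l2 = float(selim[0]), float(selim[1])
    if l1 > l2:
        raise ValueError("threshold limits must satisfy l1 <= l2")
    delta = np.asarray(z_full, dtype=float) - np.asarray(z_subgroup, dtype=float)
    return np.where(delta <= l1, Continuation.SUBGROUP_ONLY,
                    np.where(delta > l2, Continuation.FULL_ONLY,
                             Continuation.BOTH)).astype(np.int64)


def select_populations_futility(s_subgroup, s_full, selim):
    """Four-branch futility rule on natural-scale statistics.

    With limits ``(l1, l2)`` for the subgroup and full population:
    continue with a co-primary analysis if ``S_S < l1`` and ``S_F < l2``;
    subgroup only if ``S_S < l1`` and ``S_F >= l2``; full population only
    if ``S_S >= l1`` and ``S_F < l2``; stop for futility if both
    statistics are at or above their limit.  (Smaller is better on this
    scale for time-to-event outcomes.)
    """
    l1, l2 = float(selim[0]), float(selim[1])
    sub_go = np.asarray(s_subgroup, dtype=float) < l1
    full_go = np.asarray(s_full, dtype=float) < l2
    out = np.full(np.broadcast(sub_go, full_go).shape, int(Continuation.FUTILITY),
                  dtype=np.int64)
    out[sub_go & full_go] = Continuation.BOTH
    out[sub_go & ~full_go] = Continuation.SUBGROUP_ONLY
    out[~sub_go & full_go] = Continuation.FULL_ONLY
    return out
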