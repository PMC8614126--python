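"""Configuration, fixtures, reports and parameter grids.

Configurations use flat key-value pairs (YAML files or plain dicts)
whose names mirror the historical simulator interface for these designs
(``n.stage1``, ``effect.early``, ``outcome.final``, ``corr``, ``sprev``,
``select``, ``selim``, ``epsilon``, ``thresh``, ``ptest``, ``method``,
``fu``, ``weight``, ``level``, ``nsim``, ``seed``).  Shipped fixtures
reproduce the worked examples: a five-arm COPD dose-selection trial
(normal early outcome, normal or binary final outcome) and an oncology
enrichment trial with time-to-event endpoints.
"""

from __future__ import annotations

import copy
import io
import itertools
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .inference import CombinationWeights
from .model import EffectSpec, SampleSizePlan
from .selection import SelectionRule
from .simulator import DesignSpec, SimulationSummary, simulate

__all__ = [
    "RunConfig",
    "FIXTURES",
    "NULL_FIXTURES",
    "get_fixture",
    "parse_config",
    "run",
    "render_report",
    "run_grid",
]

logger = logging.getLogger(__name__)

_COMMON_KEYS = {
    "design", "n.stage1", "n.stage2", "effect.early", "effect.final",
    "control.early", "control.final", "outcome.early", "outcome.final",
    "corr", "nsim", "seed", "method", "weight", "level", "select",
}
_TREATSEL_KEYS = _COMMON_KEYS | {"epsilon", "thresh", "ptest", "fu"}
_SUBPOP_KEYS = _COMMON_KEYS | {"n.enrich", "sprev", "sprev.fixed", "selim"}
_REQUIRED_KEYS = ("n.stage1", "n.stage2", "effect.early", "effect.final")

#: map from the numeric treatment-selection codes to rule names
_SELECT_CODES = {0: "all", 1: "best1", 2: "best2", 3: "best3",
                 4: "epsilon", 5: "random1", 6: "threshold"}


@dataclass(frozen=True)
class RunConfig:
    """A validated design plus output plumbing."""

    spec: DesignSpec
    format: str = "text"
    out: str | None = None
    fixture: str | None = None
    applied_defaults: tuple = ()
    raw: dict | None = None


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

FIXTURES = {
    # five-arm COPD dose selection, always carrying the best two doses
    "copd-setting1": {
        "design": "treatsel",
        "n.stage1": 100, "n.stage2": 300,
        "effect.early": [0, 0.68, 0.82, 0.95, 0.91],
        "effect.final": [0, 0.13, 0.17, 0.23, 0.20],
        "outcome.early": "N", "outcome.final": "N",
        "corr": 0.4, "select": 2, "level": 0.025,
        "nsim": 10000, "ptest": [3, 4],
    },
    # threshold selection on the early statistics with futility stopping
    "copd-setting2": {
        "design": "treatsel",
        "n.stage1": 40, "n.stage2": 400,
        "effect.early": [0, 0.68, 0.82, 0.95, 0.91],
        "effect.final": [0, 0.13, 0.17, 0.23, 0.20],
        "outcome.early": "N", "outcome.final": "N",
        "corr": 0.4, "select": 6, "thresh": 3, "level": 0.025,
        "nsim": 10000, "ptest": [3, 4],
    },
    # binary final outcome (26-week failure rates per arm)
    "copd-setting3": {
        "design": "treatsel",
        "n.stage1": 100, "n.stage2": 300,
        "effect.early": [0, 0.68, 0.82, 0.95, 0.91],
        "effect.final": [0.50, 0.45, 0.45, 0.40, 0.40],
        "outcome.early": "N", "outcome.final": "B",
        "corr": 0.4, "select": 2, "level": 0.025,
        "nsim": 10000, "ptest": [3, 4],
    },
    # oncology enrichment design, hazard ratios 0.6 (subgroup) / 0.9 (full)
    "oncology-subgroup": {
        "design": "subpop",
        "n.stage1": 100, "n.enrich": 200, "n.stage2": 300,
        "effect.early": [0.6, 0.9], "effect.final": [0.6, 0.9],
        "outcome.early": "T", "outcome.final": "T",
        "sprev": 0.3, "corr": 0.5, "select": "futility",
        "selim": [0, 0], "level": 0.025, "method": "CT-SD",
        "nsim": 10000,
    },
}

#: global-null variants used to audit familywise error control for every
#: method x selection-rule combination exercised by the shipped designs
NULL_FIXTURES = {
    "null-treatsel-invnorm-best2": {
        "design": "treatsel", "n.stage1": 100, "n.stage2": 300,
        "effect.early": [0, 0, 0, 0, 0], "effect.final": [0, 0, 0, 0, 0],
        "corr": 0.4, "select": 2, "method": "invnorm",
    },
    "null-treatsel-invnorm-threshold": {
        "design": "treatsel", "n.stage1": 40, "n.stage2": 400,
        "effect.early": [0, 0, 0, 0, 0], "effect.final": [0, 0, 0, 0, 0],
        "corr": 0.4, "select": 6, "thresh": 1, "method": "invnorm",
    },
    "null-treatsel-invnorm-epsilon-fu": {
        "design": "treatsel", "n.stage1": 100, "n.stage2": 300,
        "effect.early": [0, 0, 0, 0, 0], "effect.final": [0, 0, 0, 0, 0],
        "corr": 0.4, "select": 4, "epsilon": 1, "method": "invnorm", "fu": True,
    },
    "null-treatsel-fisher-best2": {
        "design": "treatsel", "n.stage1": 100, "n.stage2": 300,
        "effect.early": [0, 0, 0, 0, 0], "effect.final": [0, 0, 0, 0, 0],
        "corr": 0.4, "select": 2, "method": "fisher",
    },
    "null-subpop-ctsd-futility-enrich": {
        "design": "subpop", "n.stage1": 100, "n.enrich": 200, "n.stage2": 300,
        "effect.early": [1.0, 1.0], "effect.final": [1.0, 1.0],
        "outcome.early": "T", "outcome.final": "T",
        "sprev": 0.3, "corr": 0.5, "select": "futility", "selim": [0, 0],
        "method": "CT-SD",
    },
    "null-subpop-ctsimes-thresh": {
        "design": "subpop", "n.stage1": 100, "n.stage2": 300,
        "effect.early": [0, 0], "effect.final": [0, 0],
        "sprev": 0.3, "corr": 0.5, "select": "thresh", "selim": [0, 0],
        "method": "CT-Simes",
    },
    "null-subpop-ctbonf-futility-varying": {
        "design": "subpop", "n.stage1": 100, "n.stage2": 300,
        "effect.early": [0, 0], "effect.final": [0, 0],
        "sprev": 0.3, "sprev.fixed": False, "corr": 0.5,
        "select": "futility", "selim": [0, 0], "method": "CT-Bonferroni",
    },
}


def get_fixture(name: str) -> dict:
    """A deep copy of a shipped fixture configuration."""
    registry = {**FIXTURES, **NULL_FIXTURES}
    if name not in registry:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(registry)}")
    return copy.deepcopy(registry[name])


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------


def _load_source(source) -> dict:
    if isinstance(source, dict):
        return copy.deepcopy(source)
    text = Path(source).read_text()
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError("config file must contain a flat key-value mapping")
    return data


def parse_config(source, *, design: str | None = None,
                 overrides: dict | None = None, format: str = "text",
                 out: str | None = None, fixture: str | None = None) -> RunConfig:
    """Validate a configuration and apply (and log) all defaults.

    ``source`` is a dict or a path to a YAML file; ``overrides`` wins
    over the file.  Raises on unknown keys, keys that do not apply to
    the design, a missing design, more than seven experimental arms, or
    invalid values.
    """
    data = _load_source(source)
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})
    if design is not None:
        declared = data.setdefault("design", design)
        if declared != design:
            raise ValueError(f"config declares design {declared!r}, expected {design!r}")
    if "design" not in data:
        raise ValueError("config must declare a design ('treatsel' or 'subpop')")
    if data["design"] not in ("treatsel", "subpop"):
        raise ValueError(f"unknown design: {data['design']!r}")
    is_treatsel = data["design"] == "treatsel"

    allowed = _TREATSEL_KEYS if is_treatsel else _SUBPOP_KEYS
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(
            f"unknown or inapplicable keys for {data['design']}: {sorted(unknown)}")
    missing = [k for k in _REQUIRED_KEYS if k not in data]
    if missing:
        raise ValueError(f"config is missing required keys: {missing}")

    defaults_applied: list = []

    def default(key, value):
        if key not in data or data[key] is None:
            data[key] = value
            defaults_applied.append(f"{key}={value!r}")
            logger.info("applied default %s = %r", key, value)
        return data[key]

    default("outcome.early", "N")
    default("outcome.final", "N")
    default("corr", 0.0)
    default("level", 0.025)
    default("nsim", 1000)
    default("seed", None)
    default("weight", None)
    default("method", "invnorm" if is_treatsel else "CT-SD")

    early = [float(x) for x in data["effect.early"]]
    final = [float(x) for x in data["effect.final"]]
    if len(early) != len(final):
        raise ValueError("effect.early and effect.final must have equal length")

    if is_treatsel:
        if len(early) < 2:
            raise ValueError("treatment selection requires a control plus >= 1 arm "
                             "(effect vectors start with the control)")
        if len(early) - 1 > 7:
            raise ValueError("designs with eight or more treatment groups are not supported")
        effects = EffectSpec(
            arm_effects_early=early[1:], arm_effects_final=final[1:],
            outcome_early=data["outcome.early"], outcome_final=data["outcome.final"],
            control_early=early[0], control_final=final[0],
            corr=float(data["corr"]), dialect="treatment")
        plan = SampleSizePlan(n1=float(data["n.stage1"]), n2=float(data["n.stage2"]))
        code = default("select", 0)
        if code not in _SELECT_CODES:
            raise ValueError(f"select must be one of {sorted(_SELECT_CODES)}")
        kind = _SELECT_CODES[code]
        rule = SelectionRule(kind=kind,
                             epsilon=float(default("epsilon", 1.0)) if kind == "epsilon" else 1.0,
                             thresh=float(default("thresh", 1.0)) if kind == "threshold" else 1.0)
        ptest = tuple(int(p) for p in default("ptest", list(range(1, len(early)))))
        followup = "complete" if default("fu", False) else "discontinued"
        extra = {"ptest": ptest, "followup": followup}
    else:
        if len(early) != 2:
            raise ValueError("subgroup selection requires (subgroup, full) effect pairs")
        if "sprev" not in data:
            raise ValueError("subgroup designs require the subgroup prevalence 'sprev'")
        effects = EffectSpec(
            arm_effects_early=early, arm_effects_final=final,
            outcome_early=data["outcome.early"], outcome_final=data["outcome.final"],
            control_early=data.get("control.early"), control_final=data.get("control.final"),
            corr=float(data["corr"]), dialect="subgroup")
        plan = SampleSizePlan(
            n1=float(data["n.stage1"]), n2=float(data["n.stage2"]),
            enrich=float(data["n.enrich"]) if data.get("n.enrich") is not None else None,
            prevalence=float(data["sprev"]),
            prevalence_fixed=bool(default("sprev.fixed", True)))
        kind = default("select", "thresh")
        if kind not in ("thresh", "futility"):
            raise ValueError("subgroup select must be 'thresh' or 'futility'")
        if "selim" not in data:
            raise ValueError("subgroup selection rules require 'selim' limits")
        rule = SelectionRule(kind="threshold" if kind == "thresh" else "futility",
                             selim=tuple(float(x) for x in data["selim"]))
        extra = {}

    weights = None
    if data["weight"] is not None:
        w1sq = float(data["weight"])
        if not 0.0 <= w1sq <= 1.0:
            raise ValueError("weight (the squared stage-1 weight) must lie in [0, 1]")
        weights = CombinationWeights(np.sqrt(w1sq), np.sqrt(1.0 - w1sq))

    spec = DesignSpec(
        design="treatment" if is_treatsel else "subgroup",
        effects=effects, plan=plan, rule=rule, method=data["method"],
        weights=weights, alpha=float(data["level"]), nsim=int(data["nsim"]),
        seed=data["seed"], **extra)
    return RunConfig(spec=spec, format=format, out=out, fixture=fixture,
                     applied_defaults=tuple(defaults_applied), raw=data)


def run(config: RunConfig) -> SimulationSummary:
    """Simulate the configured design."""
    return simulate(config.spec)


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------


def _fmt(x: float, dp: int) -> str:
    """Fixed-precision format with trailing zeros trimmed (1.60 -> '1.6', 3.0 -> '3')."""
    s = f"{round(float(x) + 0.0, dp):.{dp}f}"
    return s.rstrip("0").rstrip(".") if "." in s else s


def _fmt_vec(values, dp: int) -> str:
    return " ".join(_fmt(v, dp) for v in np.atleast_1d(values))


def _text_report(summary: SimulationSummary) -> str:
    buf = io.StringIO()
    w = summary.weights
    exp = summary.expectations
    print("simulation of test statistics:", file=buf)
    if summary.design == "treatment":
        print(f"expectation early = {_fmt_vec(exp['early'], 1)}", file=buf)
        print(f"expectation final stage 1 = {_fmt_vec(exp['final_stage1'], 1)} "
              f"and stage 2 = {_fmt_vec(exp['final_stage2'], 1)}", file=buf)
        print(f"weights: stage 1 = {_fmt(w[0], 2)} and stage 2 = {_fmt(w[1], 2)}", file=buf)
        print(file=buf)
        k = len(summary.per_arm_selection)
        print("number of treatments selected at stage 1:", file=buf)
        print("      n      %", file=buf)
        for m, count in enumerate(summary.n_selected, start=1):
            print(f"  {m} {count:>6} {100 * count / summary.nsim:>6.2f}", file=buf)
        print(f"  Total {summary.continuing:>6} {100 * summary.continuing / summary.nsim:>6.2f}",
              file=buf)
        print(file=buf)
        print("treatment selection at stage 1:", file=buf)
        print("      n      %", file=buf)
        for arm in range(k):
            count = summary.per_arm_selection[arm]
            print(f"  {arm + 1} {count:>6} {100 * count / summary.nsim:>6.2f}", file=buf)
        print(file=buf)
        print("hypothesis rejection at study endpoint:", file=buf)
        print("      n      %", file=buf)
        for arm in range(k):
            count = summary.rejections[arm]
            print(f"  H{arm + 1} {count:>6} {100 * count / summary.nsim:>6.2f}", file=buf)
        print(file=buf)
        label = " and/or ".join(f"H{p}" for p in summary.ptest)
        pct = 100 * summary.ptest_rejections / summary.nsim
        print(f"reject {label} = {summary.ptest_rejections} : {_fmt(pct, 2)}%", file=buf)
    else:
        print(f"expectation early: sub-pop = {_fmt(exp['early'][0], 2)} : "
              f"full-pop = {_fmt(exp['early'][1], 2)}", file=buf)
        print(f"expectation final stage 1: sub-pop = {_fmt(exp['final_stage1'][0], 2)} : "
              f"full-pop = {_fmt(exp['final_stage1'][1], 2)}", file=buf)
        print(f"expectation final stage 2: sub-pop only = {_fmt(exp['final_stage2_only'][0], 2)} : "
              f"full-pop only = {_fmt(exp['final_stage2_only'][1], 2)}", file=buf)
        print(f"expectation final stage 2, both groups selected: "
              f"sub-pop = {_fmt(exp['final_stage2_both'][0], 2)} : "
              f"full-pop = {_fmt(exp['final_stage2_both'][1], 2)}", file=buf)
        print(f"weights: stage 1 = {_fmt(w[0], 2)} and stage 2 = {_fmt(w[1], 2)}", file=buf)
        print(file=buf)
        print("hypotheses rejected and group selection options at stage 1 (n):", file=buf)
        print("        Hs    Hf  Hs+Hf  Hs+f     n    n%", file=buf)
        totals = {key: 0 for key in ("Hs", "Hf", "Hs+Hf", "Hs|f")}
        for row in ("sub", "full", "both"):
            rec = summary.table[row]
            for key in totals:
                totals[key] += rec[key]
            print(f"{row:<5} {rec['Hs']:>5} {rec['Hf']:>5} {rec['Hs+Hf']:>6} "
                  f"{rec['Hs|f']:>5} {rec['n']:>5} {100 * rec['n'] / summary.nsim:>5.2f}",
                  file=buf)
        print(f"total {totals['Hs']:>5} {totals['Hf']:>5} {totals['Hs+Hf']:>6} "
              f"{totals['Hs|f']:>5} {summary.continuing:>5}     -", file=buf)
        print(f"%     {100 * totals['Hs'] / summary.nsim:>5.2f} "
              f"{100 * totals['Hf'] / summary.nsim:>5.2f} "
              f"{100 * totals['Hs+Hf'] / summary.nsim:>6.2f} "
              f"{100 * totals['Hs|f'] / summary.nsim:>5.2f} "
              f"{100 * summary.continuing / summary.nsim:>5.2f}     -", file=buf)
        print(f"reject Hs and/or Hf = {_fmt(100 * totals['Hs|f'] / summary.nsim, 2)}%",
              file=buf)
    return buf.getvalue()


def render_report(summary: SimulationSummary, format: str = "text") -> str:
    """Render a summary as text (the printed report), JSON or CSV.

    The JSON form is a lossless, deterministic serialization of
    :meth:`SimulationSummary.to_dict`; CSV is a flat key/value table.
    """
    if format == "text":
        return _text_report(summary)
    if format == "json":
        return json.dumps(summary.to_dict(), indent=2, sort_keys=True) + "\n"
    if format == "csv":
        flat = pd.json_normalize(summary.to_dict(), sep=".").iloc[0]
        frame = flat.rename_axis("key").reset_index(name="value")
        frame["value"] = frame["value"].map(
            lambda v: json.dumps(v) if isinstance(v, list) else v)
        return frame.to_csv(index=False)
    raise ValueError(f"unknown report format: {format!r}")


# ---------------------------------------------------------------------------
# grids
# ---------------------------------------------------------------------------

_HEADLINE_TREATMENT = ("ptest_pct", "continuing_pct", "expected_N")
_HEADLINE_SUBGROUP = ("sub_pct", "full_pct", "both_pct", "futility_pct", "power_pct")


def run_grid(base: RunConfig, sweep: dict) -> pd.DataFrame:
    """One simulation per grid point of the swept configuration keys.

    ``sweep`` maps config keys (e.g. ``"thresh"``, ``"n.stage1"``,
    ``"selim"``) to sequences of values; the cartesian product is run
    with the shared root seed of the base configuration.  Infeasible
    points are reported in an ``error`` column rather than raised.
    """
    keys = list(sweep)
    rows = []
    for combo in itertools.product(*(list(sweep[k]) for k in keys)):
        point = dict(zip(keys, combo))
        row = {k: (tuple(v) if isinstance(v, (list, tuple)) else v)
               for k, v in point.items()}
        try:
            cfg = parse_config({**(base.raw or {}), **point},
                               format=base.format)
            summary = run(cfg)
        except ValueError as err:
            row["error"] = str(err)
            rows.append(row)
            continue
        row["error"] = ""
        if summary.design == "treatment":
            row["ptest_pct"] = 100 * summary.ptest_rejections / summary.nsim
            row["continuing_pct"] = 100 * summary.continuing / summary.nsim
            row["expected_N"] = summary.expected_sample_size_
        else:
            counts = summary.branch_counts
            row["sub_pct"] = 100 * counts["sub"] / summary.nsim
            row["full_pct"] = 100 * counts["full"] / summary.nsim
            row["both_pct"] = 100 * counts["both"] / summary.nsim
            row["futility_pct"] = 100 * counts["futility"] / summary.nsim
            power = sum(summary.table[r]["Hs|f"] for r in ("sub", "full", "both"))
            row["power_pct"] = 100 * power / summary.nsim
            row["expected_N"] = summary.expected_sample_size_
        rows.append(row)
    return pd.DataFrame(rows)
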