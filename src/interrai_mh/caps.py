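"""Clinical Assessment Protocol (CAP) triggering.

A CAP couples a care-planning guideline with a triggering algorithm that
classifies an assessed person into 0 (not triggered), 1 or 2 intervention
levels from item values and scale scores.  Trigger rules here are
declarative predicates loaded from config; the shipped defaults are
documented, non-canonical stand-ins for the licensed algorithms, but the
applicability matrix (which instrument triggers which CAP, and how many
levels each has) follows the published protocol list exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .errors import ConfigError
from .registry import AssessmentRecord, Registry
from .scales import ScaleDef, ScaleScore, _OPS

CAP_GROUPS = ("safety", "social life", "economic issues", "autonomy", "health promotion")


@dataclass(frozen=True)
class CapDef:
    name: str
    group: str
    n_levels: int
    level_focus: tuple[str, ...]
    applies_to: frozenset[str]
    rules: tuple[tuple[int, Mapping], ...]  # (level, predicate), highest level first

    def __post_init__(self):
        if self.group not in CAP_GROUPS:
            raise ConfigError(f"CAP {self.name!r}: unknown group {self.group!r}")
        if self.n_levels not in (1, 2):
            raise ConfigError(f"CAP {self.name!r}: n_levels must be 1 or 2")
        levels = [lv for lv, _ in self.rules]
        if levels != sorted(levels, reverse=True) or set(levels) != set(
            range(1, self.n_levels + 1)
        ):
            raise ConfigError(f"CAP {self.name!r}: rules must cover levels 1..{self.n_levels}")


@dataclass(frozen=True)
class CapResult:
    cap: str
    level: int  # 0 = not triggered
    inputs_complete: bool


def _predicate_vars(pred: Mapping) -> set[str]:
    if "var" in pred:
        return {pred["var"]}
    key = "any" if "any" in pred else "all" if "all" in pred else None
    if key is None:
        raise ConfigError(f"malformed CAP predicate {pred!r}")
    out: set[str] = set()
    for sub in pred[key]:
        out |= _predicate_vars(sub)
    return out


def _eval_predicate(pred: Mapping, lookup) -> tuple[bool, bool]:
    """Returns (satisfied, all inputs observed); missing inputs never satisfy."""
    if "var" in pred:
        value = lookup(pred["var"])
        if value is None:
            return False, False
        return _OPS[pred["op"]](value, pred["value"]), True
    if "any" in pred:
        complete, hit = True, False
        for sub in pred["any"]:
            ok, comp = _eval_predicate(sub, lookup)
            complete &= comp
            hit |= ok
        return hit, complete
    if "all" in pred:
        complete, hit = True, True
        for sub in pred["all"]:
            ok, comp = _eval_predicate(sub, lookup)
            complete &= comp
            hit &= ok
        return hit, complete
    raise ConfigError(f"malformed CAP predicate {pred!r}")


def load_cap_defs(
    config: Sequence[Mapping] | None = None,
    registry: Registry | None = None,
    scale_defs: Mapping[str, ScaleDef] | None = None,
) -> list[CapDef]:
    """Load CAP definitions; with a registry and scale defs, every rule input
    is checked to be available on every instrument the CAP applies to."""
    if config is None:
        from .defaults import DEFAULT_CAP_CONFIG

        config = DEFAULT_CAP_CONFIG
    defs = []
    for entry in config:
        rules = tuple(
            sorted(((int(lv), pred) for lv, pred in entry["rules"].items()), reverse=True)
        )
        cap = CapDef(
            name=entry["name"],
            group=entry["group"],
            n_levels=int(entry["n_levels"]),
            level_focus=tuple(entry.get("level_focus", ())),
            applies_to=frozenset(entry["applies_to"]),
            rules=rules,
        )
        if registry is not None and scale_defs is not None:
            for inst in cap.applies_to:
                spec = registry[inst]
                for _, pred in cap.rules:
                    for var in _predicate_vars(pred):
                        kind, _, name = var.partition(":")
                        if kind == "item" and name not in spec.item_codes:
                            raise ConfigError(
                                f"CAP {cap.name!r}: item {name!r} not on instrument {inst}"
                            )
                        if kind == "scale" and (
                            name not in scale_defs
                            or inst not in scale_defs[name].instruments
                        ):
                            raise ConfigError(
                                f"CAP {cap.name!r}: scale {name!r} not scored on instrument {inst}"
                            )
        defs.append(cap)
    return defs


def evaluate_caps(
    record: AssessmentRecord,
    scores: Mapping[str, ScaleScore],
    defs: Sequence[CapDef],
) -> list[CapResult]:
    """Evaluate every CAP applicable to the record's instrument.

    Levels are tested top-down (highest first); the first satisfied rule
    wins.  Missing inputs never satisfy a rule and are reported through
    ``inputs_complete``.
    """

    def lookup(var: str):
        kind, _, name = var.partition(":")
        if kind == "item":
            return record.responses.get(name)
        score = scores.get(name)
        return score.value if score is not None else None

    out = []
    for cap in defs:
        if record.instrument not in cap.applies_to:
            continue
        level, complete = 0, True
        for lv, pred in cap.rules:
            hit, comp = _eval_predicate(pred, lookup)
            complete &= comp
            if hit:
                level = lv
                break
        out.append(CapResult(cap=cap.name, level=level, inputs_complete=complete))
    return out


def triggering_rates(
    results: Sequence[tuple[CapResult, Mapping]],
    stratifier: str,
) -> pd.DataFrame:
    """Tabulate trigger rates per CAP x level x stratum.

    ``results`` pairs each CapResult with the covariates of its record.
    Rates come with numerator and denominator; the denominator is all
    assessed records in the stratum, with a completeness column reporting
    the share whose rule inputs were fully observed.
    """
    rows = []
    for res, cov in results:
        if stratifier not in cov:
            raise KeyError(f"stratifier {stratifier!r} missing from covariates")
        rows.append(
            {
                "cap": res.cap,
                "level": res.level,
                "stratum": cov[stratifier],
                "inputs_complete": res.inputs_complete,
            }
        )
    df = pd.DataFrame(rows)
    out = []
    for (cap, stratum), grp in df.groupby(["cap", "stratum"], sort=True):
        denom = len(grp)
        max_level = int(grp["level"].max()) if denom else 0
        for level in range(1, max(2, max_level) + 1):
            num = int((grp["level"] == level).sum())
            out.append(
                {
                    "cap": cap,
                    "level": level,
                    "stratum": stratum,
                    "numerator": num,
                    "denominator": denom,
                    "rate": num / denom if denom else float("nan"),
                    "complete_share": float(grp["inputs_complete"].mean()),
                }
            )
    return pd.DataFrame(out)
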