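"""Summary-scale scoring: parallel-form sum scales and decision-tree scales.

Two scale families are supported.  *Sum scales* add a fixed component list
of ordinal items (e.g. the Positive Symptoms Scale: hallucinations, command
hallucinations, delusions, abnormal thought process, 0-12).  *Decision-tree
scales* classify a record by walking a branching rule over items and
sub-scale scores into an ordinal severity from 0 (intact) to 6 (very
severe) — the Cognitive Performance Scale, Risk of Harm to Others,
Self-Care Index and Severity of Self-harm Scale.

Trees are data, not code: a :class:`TreeSpec` is loaded from config, so the
shipped default trees can be swapped for licensed specifications.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .errors import ConfigError
from .registry import AssessmentRecord, InstrumentSpec, Registry

_OPS = {
    ">=": lambda a, b: a >= b,
    ">": lambda a, b: a > b,
    "<=": lambda a, b: a <= b,
    "<": lambda a, b: a < b,
    "==": lambda a, b: a == b,
}

TREE_MIN, TREE_MAX = 0, 6


@dataclass(frozen=True)
class TreeNode:
    """One binary decision: compare an item or sub-scale against a cutpoint."""

    var: str  # "item:<code>" or "scale:<name>"
    op: str
    value: int
    then: "TreeNode | int"
    otherwise: "TreeNode | int"

    def variables(self) -> set[str]:
        out = {self.var}
        for branch in (self.then, self.otherwise):
            if isinstance(branch, TreeNode):
                out |= branch.variables()
        return out

    def leaves(self) -> set[int]:
        out: set[int] = set()
        for branch in (self.then, self.otherwise):
            if isinstance(branch, TreeNode):
                out |= branch.leaves()
            else:
                out.add(branch)
        return out


def parse_tree(node: Mapping | int) -> TreeNode | int:
    """Parse a nested-dict tree config into a :class:`TreeNode` structure."""
    if isinstance(node, int):
        if not (TREE_MIN <= node <= TREE_MAX):
            raise ConfigError(f"tree leaf {node} outside [{TREE_MIN}, {TREE_MAX}]")
        return node
    if not isinstance(node, Mapping):
        raise ConfigError(f"tree node must be a mapping or integer leaf, got {node!r}")
    op = node["op"]
    if op not in _OPS:
        raise ConfigError(f"unknown tree operator {op!r}")
    var = node["var"]
    if not (var.startswith("item:") or var.startswith("scale:")):
        raise ConfigError(f"tree variable {var!r} must be prefixed item: or scale:")
    return TreeNode(
        var=var,
        op=op,
        value=int(node["value"]),
        then=parse_tree(node["then"]),
        otherwise=parse_tree(node["else"]),
    )


@dataclass(frozen=True)
class ScaleDef:
    """Declarative definition of one summary scale."""

    name: str
    kind: str  # "sum" | "decision_tree"
    components: tuple[str, ...]
    out_min: int
    out_max: int
    instruments: frozenset[str]
    tree: TreeNode | int | None = None
    subscales: tuple[str, ...] = ()
    component_cap: int | None = None  # per-component ceiling (alternate codings)

    def __post_init__(self):
        if self.kind not in ("sum", "decision_tree"):
            raise ConfigError(f"scale {self.name!r}: unknown kind {self.kind!r}")
        if self.kind == "decision_tree":
            if self.tree is None:
                raise ConfigError(f"scale {self.name!r}: decision_tree requires a tree")
            if (self.out_min, self.out_max) != (TREE_MIN, TREE_MAX):
                raise ConfigError(f"scale {self.name!r}: decision-tree range must be 0-6")
            allowed = {f"item:{c}" for c in self.components} | {
                f"scale:{s}" for s in self.subscales
            }
            if isinstance(self.tree, TreeNode):
                stray = self.tree.variables() - allowed
                if stray:
                    raise ConfigError(
                        f"scale {self.name!r}: tree references undeclared variables {sorted(stray)}"
                    )
                bad = {v for v in self.tree.leaves() if not TREE_MIN <= v <= TREE_MAX}
                if bad:
                    raise ConfigError(f"scale {self.name!r}: leaves {sorted(bad)} out of range")


@dataclass(frozen=True)
class ScaleScore:
    scale: str
    value: int | None
    n_missing_components: int = 0

    @property
    def complete(self) -> bool:
        return self.value is not None and self.n_missing_components == 0


def load_scale_defs(
    config: Sequence[Mapping] | None = None, registry: Registry | None = None
) -> dict[str, ScaleDef]:
    """Load scale definitions from config (shipped defaults when ``None``).

    When a registry is supplied, component coding ranges are taken from it
    and each component is checked against the instruments the scale claims;
    sum-scale output maxima are then the sum of component maxima by
    construction.
    """
    if config is None:
        from .defaults import DEFAULT_SCALE_CONFIG

        config = DEFAULT_SCALE_CONFIG
    if registry is None:
        from .registry import build_registry

        registry = build_registry()

    defs: dict[str, ScaleDef] = {}
    for entry in config:
        name = entry["name"]
        components = tuple(entry["components"])
        instruments = frozenset(entry.get("instruments", ()))
        cap = entry.get("component_cap")
        for inst_code in instruments:
            spec = registry[inst_code]
            missing = [c for c in components if c not in spec.item_codes]
            if missing:
                raise ConfigError(
                    f"scale {name!r}: components {missing} absent from instrument {inst_code}"
                )
        if entry["kind"] == "sum":
            ref = next(iter(instruments), None)
            spec = registry[ref] if ref else None
            out_max = 0
            for c in components:
                item_max = spec.item(c).max_code if spec else 3
                out_max += min(item_max, cap) if cap is not None else item_max
            defs[name] = ScaleDef(
                name=name,
                kind="sum",
                components=components,
                out_min=0,
                out_max=out_max,
                instruments=instruments,
                component_cap=cap,
            )
        else:
            defs[name] = ScaleDef(
                name=name,
                kind="decision_tree",
                components=components,
                out_min=TREE_MIN,
                out_max=TREE_MAX,
                instruments=instruments,
                tree=parse_tree(entry["tree"]),
                subscales=tuple(entry.get("subscales", ())),
            )
    # sub-scales referenced by trees must exist
    for sdef in defs.values():
        for sub in sdef.subscales:
            if sub not in defs:
                raise ConfigError(f"scale {sdef.name!r}: unknown sub-scale {sub!r}")
    return defs


def score_sum_scale(
    record: AssessmentRecord, sdef: ScaleDef, *, prorate: bool = False
) -> ScaleScore:
    """Sum the component responses.

    With all components present the value is the plain sum.  Any missing
    component yields a missing value (no imputation) unless ``prorate`` is
    set, in which case the observed mean is scaled up to the full component
    count and rounded half-to-even; at least half the components must then
    be observed.
    """
    if sdef.kind != "sum":
        raise ConfigError(f"scale {sdef.name!r} is not a sum scale")
    values = []
    n_missing = 0
    for c in sdef.components:
        v = record.responses.get(c)
        if v is None:
            n_missing += 1
        else:
            values.append(min(v, sdef.component_cap) if sdef.component_cap is not None else v)
    if n_missing == 0:
        return ScaleScore(sdef.name, int(sum(values)), 0)
    if prorate and values and len(values) * 2 >= len(sdef.components):
        scaled = sum(values) * len(sdef.components) / len(values)
        # bankers' rounding, clipped into the printed range
        value = min(max(round(scaled), sdef.out_min), sdef.out_max)
        return ScaleScore(sdef.name, int(value), n_missing)
    return ScaleScore(sdef.name, None, n_missing)


def score_tree_scale(
    record: AssessmentRecord,
    sdef: ScaleDef,
    subscale_scores: Mapping[str, ScaleScore] | None = None,
    all_defs: Mapping[str, ScaleDef] | None = None,
) -> ScaleScore:
    """Walk the decision tree to an integer leaf in [0, 6].

    Sub-scale scores may be passed in; any that are absent are computed on
    demand from ``all_defs``.  A condition touching a missing item or an
    incomplete sub-scale yields a missing score.
    """
    if sdef.kind != "decision_tree":
        raise ConfigError(f"scale {sdef.name!r} is not a decision-tree scale")
    resolved: dict[str, ScaleScore] = dict(subscale_scores or {})
    for sub in sdef.subscales:
        if sub not in resolved:
            if all_defs is None or sub not in all_defs:
                raise ConfigError(f"scale {sdef.name!r}: sub-scale {sub!r} unavailable")
            sub_def = all_defs[sub]
            resolved[sub] = (
                score_sum_scale(record, sub_def)
                if sub_def.kind == "sum"
                else score_tree_scale(record, sub_def, resolved, all_defs)
            )

    node = sdef.tree
    n_missing = sum(1 for c in sdef.components if c not in record.responses)
    while isinstance(node, TreeNode):
        kind, _, name = node.var.partition(":")
        if kind == "item":
            value = record.responses.get(name)
        else:
            score = resolved[name]
            value = score.value
        if value is None:
            return ScaleScore(sdef.name, None, max(n_missing, 1))
        node = node.then if _OPS[node.op](value, node.value) else node.otherwise
    return ScaleScore(sdef.name, int(node), n_missing)


def score_all(
    record: AssessmentRecord,
    defs: Mapping[str, ScaleDef],
    *,
    prorate: bool = False,
) -> dict[str, ScaleScore]:
    """Score every scale applicable to the record's instrument.

    Inapplicable scales are omitted entirely — never emitted as zero.
    Sum scales are scored first so decision trees can consume them.
    """
    applicable = {n: d for n, d in defs.items() if record.instrument in d.instruments}
    out: dict[str, ScaleScore] = {}
    for name, sdef in applicable.items():
        if sdef.kind == "sum":
            out[name] = score_sum_scale(record, sdef, prorate=prorate)
    # trees in dependency order (sub-scales may themselves be trees)
    pending = [d for d in applicable.values() if d.kind == "decision_tree"]
    guard = len(pending) + 1
    while pending and guard:
        guard -= 1
        still = []
        for sdef in pending:
            if all(s in out or s not in applicable for s in sdef.subscales):
                out[sdef.name] = score_tree_scale(record, sdef, out, defs)
            else:
                still.append(sdef)
        pending = still
    if pending:
        raise ConfigError(f"circular sub-scale dependencies: {[d.name for d in pending]}")
    return out


def scores_to_frame(records, defs, *, prorate: bool = False):
    """Long-format scores table: person_id, instrument, reason, date, scale, value, complete."""
    import pandas as pd

    rows = []
    for rec in records:
        for name, score in score_all(rec, defs, prorate=prorate).items():
            rows.append(
                {
                    "person_id": rec.person_id,
                    "instrument": rec.instrument,
                    "reason": rec.reason,
                    "date": rec.date.isoformat(),
                    "scale": name,
                    "value": score.value,
                    "complete": score.complete,
                }
            )
    return pd.DataFrame(
        rows, columns=["person_id", "instrument", "reason", "date", "scale", "value", "complete"]
    )
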