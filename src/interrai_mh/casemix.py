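"""Per-diem case-mix application and trend summaries.

A case-mix system has two parts: a classifier grouping service users by
clinical characteristics, and a table of case-mix indexes (CMIs) — ratio-
level weights expressing relative per-diem resource intensity — one per
group.  The inpatient-psychiatry classifier in production use (47 groups,
roughly 100 input variables, an 8.4:1 CMI spread) is licensed and
unpublished, so this module ships the surrounding machinery with a
documented toy grouper whose default CMI table reproduces the 8.4:1
spread for testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .registry import AssessmentRecord
from .scales import ScaleDef, score_all

GroupingFn = Callable[[AssessmentRecord, Mapping], str | None]


@dataclass(frozen=True)
class CmiTable:
    """Group label -> case-mix index (positive, ratio scale)."""

    groups: Mapping[str, float]

    def __post_init__(self):
        if not self.groups:
            raise ConfigError("CMI table is empty")
        bad = {g: v for g, v in self.groups.items() if not v > 0}
        if bad:
            raise ConfigError(f"CMIs must be positive: {bad}")

    def __getitem__(self, group: str) -> float:
        return self.groups[group]

    def spread(self) -> float:
        """Max/min CMI ratio across groups."""
        values = list(self.groups.values())
        return max(values) / min(values)

    @classmethod
    def from_csv(cls, path) -> "CmiTable":
        df = pd.read_csv(path)
        return cls(dict(zip(df["group"].astype(str), df["cmi"].astype(float))))


def default_cmi_table() -> CmiTable:
    from .defaults import DEFAULT_CMI_TABLE

    return CmiTable(dict(DEFAULT_CMI_TABLE))


def toy_grouper(record: AssessmentRecord, scores: Mapping) -> str | None:
    """Nine-group toy classifier: cognitive band x positive-symptom band.

    Bands: Cognitive Performance 0 / 1-2 / 3-6 and Positive Symptoms
    0 / 1-5 / 6-12.  Returns ``None`` when either input score is missing.
    """
    cps = scores.get("cognitive_performance")
    psy = scores.get("positive_symptoms")
    cps_v = getattr(cps, "value", cps)
    psy_v = getattr(psy, "value", psy)
    if cps_v is None or psy_v is None:
        return None
    cog = 0 if cps_v == 0 else 1 if cps_v <= 2 else 2
    pos = 0 if psy_v == 0 else 1 if psy_v <= 5 else 2
    return f"COG{cog}-PSY{pos}"


def apply_cmi(
    records: Iterable[AssessmentRecord],
    grouper: GroupingFn,
    table: CmiTable,
    scale_defs: Mapping[str, ScaleDef] | None = None,
) -> tuple[pd.DataFrame, int]:
    """Assign each record a case-mix group and CMI.

    Returns (assignment table, number of unassignable records).  Records
    the grouper cannot classify (missing inputs) are excluded and counted;
    a group label absent from the CMI table is a hard error.
    """
    if scale_defs is None:
        from .scales import load_scale_defs

        scale_defs = load_scale_defs()
    rows = []
    n_unassignable = 0
    for rec in records:
        scores = score_all(rec, scale_defs)
        group = grouper(rec, scores)
        if group is None:
            n_unassignable += 1
            continue
        if group not in table.groups:
            raise ConfigError(f"group label {group!r} not in CMI table")
        rows.append(
            {
                "person_id": rec.person_id,
                "reason": rec.reason,
                "period": rec.date.year,
                "group": group,
                "cmi": table[group],
            }
        )
    return (
        pd.DataFrame(rows, columns=["person_id", "reason", "period", "group", "cmi"]),
        n_unassignable,
    )


def percent_change(earlier: float, later: float) -> float:
    """Percent change between two period means, displayed to one decimal.

    Asymmetric by definition: the earlier period is the denominator.
    """
    if earlier == 0:
        raise ConfigError("percent change undefined for a zero baseline mean")
    return round((later - earlier) / earlier * 100.0, 1)


def summarize_cmi_trend(
    assignments: pd.DataFrame,
    compare_periods: tuple[int, int] | None = None,
) -> dict:
    """Mean CMI with normal-approximation 95% CI per reason x period.

    ``compare_periods`` names (earlier, later) periods for a per-reason
    percent-change summary of mean admission/discharge resource intensity.
    Empty cells are reported as undefined rather than fabricated.
    """
    cells = []
    for (reason, period), grp in assignments.groupby(["reason", "period"], sort=True):
        n = len(grp)
        mean = float(grp["cmi"].mean())
        if n > 1:
            half = 1.959963984540054 * float(grp["cmi"].std(ddof=1)) / np.sqrt(n)
        else:
            half = float("nan")
        cells.append(
            {
                "reason": reason,
                "period": period,
                "n": n,
                "mean_cmi": mean,
                "ci_low": mean - half,
                "ci_high": mean + half,
            }
        )
    table = pd.DataFrame(cells)
    out = {"cells": table}
    if compare_periods is not None:
        earlier, later = compare_periods
        changes = {}
        for reason, grp in table.groupby("reason"):
            by_period = grp.set_index("period")["mean_cmi"]
            if earlier in by_period.index and later in by_period.index:
                changes[reason] = percent_change(
                    float(by_period[earlier]), float(by_period[later])
                )
            else:
                changes[reason] = None  # undefined: empty cell
        out["percent_change"] = changes
    return out
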