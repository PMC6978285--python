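"""Reading and writing assessment records (JSON-lines and wide CSV).

Both formats round-trip bit-exactly.  In CSV, one column per item code
(sorted, deterministic order), empty cell = item not assessed; covariate
values are JSON-encoded per cell so types survive the trip.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable, Sequence

from .errors import RecordParseError, RegistryError
from .registry import AssessmentRecord, Registry, validate_record

_FIXED_COLUMNS = ("person_id", "instrument", "reason", "date")
_COV_PREFIX = "cov_"


def read_assessments(path: str | Path, format: str | None = None) -> list[AssessmentRecord]:
    """Read records from ``path``; ``format`` is jsonl or csv (inferred from suffix)."""
    path = Path(path)
    fmt = format or ("csv" if path.suffix == ".csv" else "jsonl")
    if fmt == "jsonl":
        return _read_jsonl(path)
    if fmt == "csv":
        return _read_csv(path)
    raise ValueError(f"unknown format {fmt!r}")


def write_assessments(
    records: Sequence[AssessmentRecord],
    path: str | Path,
    format: str | None = None,
    registry: Registry | None = None,
) -> None:
    """Write records; refuses to write if any record fails registry validation."""
    path = Path(path)
    fmt = format or ("csv" if path.suffix == ".csv" else "jsonl")
    if registry is not None:
        problems = []
        for i, rec in enumerate(records):
            if rec.instrument not in registry:
                raise RegistryError(f"record {i}: unknown instrument {rec.instrument!r}")
            violations = validate_record(rec, registry[rec.instrument])
            if violations:
                problems.append((i, violations))
        if problems:
            i, violations = problems[0]
            raise RegistryError(
                f"refusing to write: {len(problems)} invalid record(s); first is record {i}: "
                + "; ".join(v.message for v in violations)
            )
    if fmt == "jsonl":
        _write_jsonl(records, path)
    elif fmt == "csv":
        _write_csv(records, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def _record_to_obj(rec: AssessmentRecord) -> dict:
    return {
        "person_id": rec.person_id,
        "instrument": rec.instrument,
        "reason": rec.reason,
        "date": rec.date.isoformat(),
        "responses": {k: rec.responses[k] for k in sorted(rec.responses)},
        "covariates": {k: rec.covariates[k] for k in sorted(rec.covariates)},
    }


def _write_jsonl(records: Iterable[AssessmentRecord], path: Path) -> None:
    with path.open("w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(_record_to_obj(rec), separators=(",", ":")) + "\n")


def _read_jsonl(path: Path) -> list[AssessmentRecord]:
    out = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise RecordParseError(f"malformed JSON: {exc.msg}", line=lineno) from exc
            responses = {}
            for item, value in obj.get("responses", {}).items():
                if not isinstance(value, int) or isinstance(value, bool):
                    raise RecordParseError(
                        f"non-integer response {value!r}", line=lineno, item=item
                    )
                responses[item] = value
            try:
                out.append(
                    AssessmentRecord(
                        person_id=obj["person_id"],
                        instrument=obj["instrument"],
                        reason=obj["reason"],
                        date=obj["date"],
                        responses=responses,
                        covariates=obj.get("covariates", {}),
                    )
                )
            except (KeyError, ValueError) as exc:
                raise RecordParseError(f"bad record: {exc}", line=lineno) from exc
    return out


def _write_csv(records: Sequence[AssessmentRecord], path: Path) -> None:
    item_cols = sorted({c for rec in records for c in rec.responses})
    cov_cols = sorted({c for rec in records for c in rec.covariates})
    header = (
        list(_FIXED_COLUMNS) + [_COV_PREFIX + c for c in cov_cols] + item_cols
    )
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for rec in records:
            row = [rec.person_id, rec.instrument, rec.reason, rec.date.isoformat()]
            for c in cov_cols:
                row.append(json.dumps(rec.covariates[c]) if c in rec.covariates else "")
            for c in item_cols:
                row.append(str(rec.responses[c]) if c in rec.responses else "")
            writer.writerow(row)


def _read_csv(path: Path) -> list[AssessmentRecord]:
    out = []
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise RecordParseError("empty file: missing CSV header", line=1) from None
        if list(header[: len(_FIXED_COLUMNS)]) != list(_FIXED_COLUMNS):
            raise RecordParseError(
                f"CSV header must start with {', '.join(_FIXED_COLUMNS)}", line=1
            )
        cov_cols = [
            (i, h[len(_COV_PREFIX) :])
            for i, h in enumerate(header)
            if h.startswith(_COV_PREFIX)
        ]
        item_cols = [
            (i, h)
            for i, h in enumerate(header)
            if i >= len(_FIXED_COLUMNS) and not h.startswith(_COV_PREFIX)
        ]
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            responses = {}
            for i, item in item_cols:
                cell = row[i] if i < len(row) else ""
                if cell == "":
                    continue
                try:
                    responses[item] = int(cell)
                except ValueError:
                    raise RecordParseError(
                        f"non-integer response {cell!r}", line=lineno, item=item
                    ) from None
            covariates = {}
            for i, name in cov_cols:
                cell = row[i] if i < len(row) else ""
                if cell == "":
                    continue
                try:
                    covariates[name] = json.loads(cell)
                except json.JSONDecodeError:
                    covariates[name] = cell
            try:
                out.append(
                    AssessmentRecord(
                        person_id=row[0],
                        instrument=row[1],
                        reason=row[2],
                        date=row[3],
                        responses=responses,
                        covariates=covariates,
                    )
                )
            except (IndexError, ValueError) as exc:
                raise RecordParseError(f"bad record: {exc}", line=lineno) from exc
    return out
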