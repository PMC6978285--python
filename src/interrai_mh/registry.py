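"""Instrument registries for the interRAI adult mental-health suite.

The suite comprises four assessment/screening instruments — the inpatient
Mental Health assessment (MH, 396 items), the Community Mental Health
assessment (CMH, 405 items), the Emergency Screener for Psychiatry
(ESP, 141 items, a subset of the MH/CMH common core) and the Brief Mental
Health Screener (BMHS, a 46-item subset of the ESP used by police and other
non-clinical first responders) — plus two supplements (Forensic, Addiction).
MH and CMH share a 330-item common core; the CMH carries 75 items the MH
does not, and the MH 66 items absent from the CMH.

Item wording and coding manuals are proprietary, so the shipped default
registry uses a synthetic item namespace whose per-domain allocation follows
the published domain counts, padded with an ``unclassified`` domain to reach
the exact published instrument totals.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping

from .errors import ConfigError, RegistryError

INSTRUMENT_CODES = ("MH", "CMH", "ESP", "BMHS", "FS", "AS")
LOOKBACKS = ("24-hour", "3-day", "7-day", "30-day", "90-day", "lifetime")
REASONS = ("admission", "review", "discharge", "crisis", "screen")

#: published instrument sizes and overlaps; asserted whenever a config
#: declares them (the shipped default config does).
PUBLISHED_COUNTS = {
    "MH": 396,
    "CMH": 405,
    "ESP": 141,
    "BMHS": 46,
    "MH&CMH": 330,
    "CMH-MH": 75,
    "MH-CMH": 66,
}


@dataclass(frozen=True)
class ItemDef:
    """One assessment item: a coded ordinal observation with a look-back window."""

    item_code: str
    domain: str
    min_code: int
    max_code: int
    lookback: str = "3-day"
    instruments: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if self.min_code < 0 or self.max_code <= self.min_code:
            raise RegistryError(
                f"item {self.item_code!r}: requires 0 <= min_code < max_code, "
                f"got [{self.min_code}, {self.max_code}]"
            )
        if self.lookback not in LOOKBACKS:
            raise RegistryError(f"item {self.item_code!r}: unknown lookback {self.lookback!r}")
        if not self.instruments:
            raise RegistryError(f"item {self.item_code!r}: belongs to no instrument")
        unknown = set(self.instruments) - set(INSTRUMENT_CODES)
        if unknown:
            raise RegistryError(f"item {self.item_code!r}: unknown instruments {sorted(unknown)}")


@dataclass(frozen=True)
class InstrumentSpec:
    """An instrument: an ordered collection of items plus a default look-back."""

    code: str
    items: tuple[ItemDef, ...]
    default_lookback: str

    def __post_init__(self):
        codes = [it.item_code for it in self.items]
        if len(codes) != len(set(codes)):
            seen, dups = set(), set()
            for c in codes:
                (dups if c in seen else seen).add(c)
            raise RegistryError(f"instrument {self.code}: duplicate item codes {sorted(dups)}")

    @property
    def item_codes(self) -> frozenset[str]:
        return frozenset(it.item_code for it in self.items)

    def item(self, code: str) -> ItemDef:
        try:
            return self._index[code]
        except AttributeError:
            object.__setattr__(self, "_index", {it.item_code: it for it in self.items})
            return self._index[code]

    def __len__(self) -> int:
        return len(self.items)


@dataclass
class AssessmentRecord:
    """One person-instrument-time observation of ordinal item responses.

    Missing items are *absent* from ``responses`` — never encoded as a
    sentinel integer — so downstream scoring can distinguish "not assessed"
    from a genuine zero.
    """

    person_id: str
    instrument: str
    reason: str
    date: _dt.date
    responses: dict[str, int] = field(default_factory=dict)
    covariates: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        if isinstance(self.date, str):
            self.date = _dt.date.fromisoformat(self.date)
        if self.reason not in REASONS:
            raise ConfigError(f"unknown assessment reason {self.reason!r}")


@dataclass(frozen=True)
class Violation:
    """A single validation failure, naming the offending item and rule."""

    item: str
    rule: str
    message: str


class Registry:
    """The full set of instrument specs, with shared-item bookkeeping."""

    def __init__(self, instruments: Iterable[InstrumentSpec]):
        self.instruments: dict[str, InstrumentSpec] = {s.code: s for s in instruments}

    def __getitem__(self, code: str) -> InstrumentSpec:
        try:
            return self.instruments[code]
        except KeyError:
            raise RegistryError(f"unknown instrument {code!r}") from None

    def __contains__(self, code: str) -> bool:
        return code in self.instruments

    def shared_items(self, a: str, b: str) -> frozenset[str]:
        return self[a].item_codes & self[b].item_codes


def _check_subsets(reg: Registry) -> None:
    if "ESP" in reg and "MH" in reg and "CMH" in reg:
        core = reg.shared_items("MH", "CMH")
        stray = reg["ESP"].item_codes - core
        if stray:
            raise RegistryError(
                f"ESP items must be a subset of the MH/CMH common core; "
                f"violations: {sorted(stray)[:5]}"
            )
    if "BMHS" in reg and "ESP" in reg:
        stray = reg["BMHS"].item_codes - reg["ESP"].item_codes
        if stray:
            raise RegistryError(
                f"BMHS items must be a subset of the ESP; violations: {sorted(stray)[:5]}"
            )


def _check_declared_counts(reg: Registry, expected: Mapping[str, int]) -> None:
    actual: dict[str, int] = {}
    for key, want in expected.items():
        if "&" in key:
            a, b = key.split("&")
            got = len(reg.shared_items(a, b))
        elif "-" in key:
            a, b = key.split("-")
            got = len(reg[a].item_codes - reg[b].item_codes)
        else:
            got = len(reg[key])
        actual[key] = got
        if got != want:
            raise RegistryError(f"registry count {key}: expected {want}, built {got}")


def build_registry(config: Mapping[str, Any] | str | Path | None = None) -> Registry:
    """Construct a :class:`Registry` from a config document.

    ``config`` may be a mapping, a path to a YAML/JSON document, or ``None``
    for the shipped default registry (published instrument totals and domain
    allocation with a synthetic item namespace).

    The config declares each item once, with its domain, coding range,
    look-back, and instrument membership; instrument totals and overlaps may
    be declared under ``expected`` and are then asserted after construction.
    """
    if config is None:
        from .defaults import default_registry_config

        config = default_registry_config()
    elif isinstance(config, (str, Path)):
        config = _load_config_file(Path(config))

    lookbacks = dict(config.get("default_lookbacks", {}))
    items_cfg = config["items"]
    per_instrument: dict[str, list[ItemDef]] = {}
    seen: dict[str, ItemDef] = {}
    for entry in items_cfg:
        item = ItemDef(
            item_code=entry["item_code"],
            domain=entry.get("domain", "unclassified"),
            min_code=int(entry.get("min_code", 0)),
            max_code=int(entry["max_code"]),
            lookback=entry.get("lookback", "3-day"),
            instruments=frozenset(entry["instruments"]),
        )
        if item.item_code in seen:
            raise RegistryError(f"duplicate item code {item.item_code!r} in config")
        seen[item.item_code] = item
        for code in item.instruments:
            per_instrument.setdefault(code, []).append(item)

    specs = [
        InstrumentSpec(
            code=code,
            items=tuple(items),
            default_lookback=lookbacks.get(
                code, "24-hour" if code in ("ESP", "BMHS") else "3-day"
            ),
        )
        for code, items in per_instrument.items()
    ]
    reg = Registry(specs)
    _check_subsets(reg)
    if "expected" in config:
        _check_declared_counts(reg, config["expected"])
    return reg


def _load_config_file(path: Path) -> dict:
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml

        return yaml.safe_load(text)
    return json.loads(text)


def validate_record(record: AssessmentRecord, spec: InstrumentSpec) -> list[Violation]:
    """Check a record's responses against an instrument spec.

    Returns an empty list iff every response key names an item registered
    for the instrument and every value lies within the item's coding range.
    A mismatched instrument code is an error, not a validation failure.
    """
    if record.instrument != spec.code:
        raise RegistryError(
            f"record instrument {record.instrument!r} does not match spec {spec.code!r}"
        )
    violations: list[Violation] = []
    codes = spec.item_codes
    for item_code in record.responses:
        value = record.responses[item_code]
        if item_code not in codes:
            violations.append(
                Violation(item_code, "unknown-item", f"{item_code!r} not in {spec.code} registry")
            )
            continue
        item = spec.item(item_code)
        if not isinstance(value, int) or isinstance(value, bool):
            violations.append(
                Violation(item_code, "non-integer", f"{item_code!r} response {value!r} not an integer")
            )
        elif not (item.min_code <= value <= item.max_code):
            violations.append(
                Violation(
                    item_code,
                    "out-of-range",
                    f"{item_code!r} response {value} outside [{item.min_code}, {item.max_code}]",
                )
            )
    return violations
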