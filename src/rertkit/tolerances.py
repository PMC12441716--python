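"""Cumulative OAR tolerance table for reirradiation: model, parser, bundled default.

The bundled table encodes the departmental reirradiation limits, organised by
anatomical region. Every tolerance is a *cumulative* EQD2 limit (prior courses
plus the new plan) with two levels: the stricter **Objective** and the
acceptable-deviation **Variation**. Special cells:

* ``open`` — an open-ended constraint (no upper bound; discuss case-by-case);
* ``none`` — the organ carries no defined constraint (flagged for discussion);
* both limit cells empty with a metric present — limits are deferred to a
  dynamic model (used for the spinal canal, whose allowance depends on the
  prior dose and the elapsed time).

Structure names ending in ``+ <m> mm`` require a planning risk volume (PRV)
expansion of that margin before the metric is evaluated.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd

from .dvh import MetricKind, MetricSpec

__all__ = [
    "Region",
    "LimitKind",
    "Limit",
    "OPEN_LIMIT",
    "NO_LIMIT",
    "ToleranceEntry",
    "ToleranceTable",
    "ToleranceParseError",
    "parse_tolerance_table",
    "write_tolerance_table",
    "default_table",
    "DEFAULT_TABLE_SHA256",
]

_CSV_COLUMNS = [
    "region", "structure", "alpha_beta",
    "metric_kind", "metric_parameter", "objective", "variation",
]

_PRV_SUFFIX = re.compile(r"\s*\+\s*(\d+(?:\.\d+)?)\s*mm\s*$")

# sha256 of the bundled departmental table, guarding against silent edits
DEFAULT_TABLE_SHA256 = (
    "d4d87d1c50775590f3fa5d69c3c32e5debe56f3bfa10e6bf58212370b5207a43"
)


class Region(str, Enum):
    THORAX = "THORAX"
    ABDOMEN = "ABDOMEN"
    PELVIS = "PELVIS"
    HEAD_AND_NECK = "HEAD_AND_NECK"
    BRAIN = "BRAIN"


class LimitKind(str, Enum):
    VALUE = "VALUE"
    OPEN = "OPEN"    # open-ended: no numeric bound, discuss case-by-case
    NONE = "NONE"    # no defined constraint / deferred


@dataclass(frozen=True)
class Limit:
    kind: LimitKind
    value: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", LimitKind(self.kind))
        if self.kind is LimitKind.VALUE:
            if self.value is None or self.value < 0:
                raise ValueError("numeric limit must be >= 0")
            object.__setattr__(self, "value", float(self.value))
        elif self.value is not None:
            raise ValueError(f"{self.kind.value} limit carries no value")

    @property
    def is_numeric(self) -> bool:
        return self.kind is LimitKind.VALUE

    def to_cell(self) -> str:
        if self.kind is LimitKind.VALUE:
            return f"{self.value:.2f}"
        return "open" if self.kind is LimitKind.OPEN else "none"


OPEN_LIMIT = Limit(LimitKind.OPEN)
NO_LIMIT = Limit(LimitKind.NONE)


class ToleranceParseError(ValueError):
    pass


@dataclass(frozen=True)
class ToleranceEntry:
    region: Region
    structure: str
    alpha_beta: float
    metric: MetricSpec | None
    objective: Limit
    variation: Limit

    def __post_init__(self) -> None:
        object.__setattr__(self, "region", Region(self.region))
        if self.alpha_beta <= 0:
            raise ValueError("alpha/beta must be > 0")
        if self.objective.is_numeric and self.variation.is_numeric:
            if self.variation.value < self.objective.value:
                raise ValueError(
                    f"{self.structure} {self.metric and self.metric.label()}: "
                    f"variation {self.variation.value} < objective "
                    f"{self.objective.value}"
                )

    @property
    def base_structure(self) -> str:
        """Structure name with any PRV suffix stripped."""
        return _PRV_SUFFIX.sub("", self.structure)

    @property
    def prv_margin_mm(self) -> float:
        m = _PRV_SUFFIX.search(self.structure)
        return float(m.group(1)) if m else 0.0

    @property
    def is_evaluable(self) -> bool:
        """Has a metric and at least one bound (numeric or open)."""
        return self.metric is not None and (
            self.objective.kind is not LimitKind.NONE
            or self.variation.kind is not LimitKind.NONE
        )

    @property
    def limits_deferred(self) -> bool:
        """Metric defined but no printed limits (dynamic tolerance, e.g. cord)."""
        return (
            self.metric is not None
            and self.objective.kind is LimitKind.NONE
            and self.variation.kind is LimitKind.NONE
        )


@dataclass(frozen=True)
class ToleranceTable:
    entries: tuple[ToleranceEntry, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(self.entries))
        seen: set[tuple] = set()
        for e in self.entries:
            key = (e.region, e.structure, e.metric)
            if key in seen:
                raise ValueError(
                    f"duplicate tolerance entry: {e.region.value}/{e.structure}/"
                    f"{e.metric and e.metric.label()}"
                )
            seen.add(key)

    def lookup(self, structure: str, region: Region) -> list[ToleranceEntry]:
        """All entries for a structure in one anatomical region (may be several
        metrics per organ); matches either the printed or the PRV-stripped name."""
        region = Region(region)
        return [
            e for e in self.entries
            if e.region is region and structure in (e.structure, e.base_structure)
        ]

    def structures(self, region: Region | None = None) -> list[str]:
        names: list[str] = []
        for e in self.entries:
            if region is not None and e.region is not Region(region):
                continue
            if e.structure not in names:
                names.append(e.structure)
        return names


def _parse_limit_cell(cell: object) -> Limit | None:
    """None means 'cell empty' (resolved by the blank-cell rules)."""
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return None
    text = str(cell).strip()
    if not text:
        return None
    low = text.lower()
    if low == "open":
        return OPEN_LIMIT
    if low in ("none", "no constraint"):
        return NO_LIMIT
    try:
        return Limit(LimitKind.VALUE, float(text))
    except ValueError as exc:
        raise ToleranceParseError(f"cannot parse limit cell {text!r}") from exc


def _row_to_entry(row: pd.Series, row_no: int) -> ToleranceEntry:
    try:
        kind_cell = row["metric_kind"]
        metric: MetricSpec | None = None
        if isinstance(kind_cell, str) and kind_cell.strip():
            kind = MetricKind(kind_cell.strip())
            param_cell = row["metric_parameter"]
            param = (
                None
                if param_cell is None or (isinstance(param_cell, float) and pd.isna(param_cell))
                or str(param_cell).strip() == ""
                else float(param_cell)
            )
            metric = MetricSpec(kind, param)
        objective = _parse_limit_cell(row["objective"])
        variation = _parse_limit_cell(row["variation"])
        if objective is None:
            objective = NO_LIMIT
        if variation is None:
            # blank variation with a numeric objective means variation = objective
            variation = objective if objective.is_numeric else NO_LIMIT
        return ToleranceEntry(
            region=Region(str(row["region"]).strip()),
            structure=str(row["structure"]).strip(),
            alpha_beta=float(row["alpha_beta"]),
            metric=metric,
            objective=objective,
            variation=variation,
        )
    except (ValueError, KeyError) as exc:
        raise ToleranceParseError(f"row {row_no}: {exc}") from exc


def parse_tolerance_table(path: str | Path, provenance: str = "") -> ToleranceTable:
    """Read a tolerance table from CSV (comma-separated, UTF-8, dot decimals)."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ToleranceParseError(f"missing columns: {missing}")
    entries = [
        _row_to_entry(row, i + 2)  # +2: 1-based with header line
        for i, (_, row) in enumerate(df.iterrows())
    ]
    return ToleranceTable(tuple(entries), provenance=provenance or str(path))


def write_tolerance_table(table: ToleranceTable, path: str | Path) -> None:
    rows = []
    for e in table.entries:
        rows.append({
            "region": e.region.value,
            "structure": e.structure,
            "alpha_beta": f"{e.alpha_beta:g}",
            "metric_kind": e.metric.kind.value if e.metric else "",
            "metric_parameter": (
                f"{e.metric.parameter:g}"
                if e.metric and e.metric.parameter is not None else ""
            ),
            "objective": e.objective.to_cell(),
            "variation": e.variation.to_cell(),
        })
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def default_table(verify_checksum: bool = True) -> ToleranceTable:
    """The bundled departmental reirradiation tolerance table."""
    ref = resources.files("rertkit") / "data" / "rert_tolerances.csv"
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if verify_checksum and digest != DEFAULT_TABLE_SHA256:
        raise ValueError(
            "bundled tolerance table failed its checksum — refusing to use a "
            f"modified clinical table (sha256 {digest})"
        )
    with resources.as_file(ref) as p:
        return parse_tolerance_table(p, provenance="bundled departmental reRT table")
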