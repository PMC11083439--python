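"""Tabular input/output and shared domain types.

Per-larva and per-station records are plain dataclasses; CSV is the only
on-disk format (RFC-4180, "." decimal, UTF-8).  Column names in input files
are configurable through a schema map whose defaults mirror the symbols used
in the larval-otolith / bulk-SIA literature (SL, DW, AGE, RADIUS, MIW,
d15N, d13C, CN).  C:N is the carbon-to-nitrogen *mass* ratio (%C/%N), the
bulk-SIA convention.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional, Sequence

import pandas as pd
import yaml

STAGE_PRE = "PRE"
STAGE_POST = "POST"
STAGES = (STAGE_PRE, STAGE_POST)


class SchemaError(ValueError):
    """A required column is missing from an input table."""


@dataclass
class LarvaRecord:
    """One larva: age, somatic/otolith metrics, isotopes, C:N, stage.

    ``stage`` is an input flag (PRE/POST developmental stage), never inferred
    from body length: pre- and post-flexion size ranges overlap in the field.
    """

    larva_id: str
    cohort: str
    station_id: str
    age_days: int
    sl_mm: float
    dw_mg: float
    radius_um: float
    miw_um: float
    stage: str
    d15n: float
    d13c: float
    cn: float
    d13c_corrected: bool = False

    def problems(self) -> list[str]:
        """Hard invariant violations (empty list when the record is valid)."""
        out = []
        if self.age_days < 1:
            out.append(f"age_days must be >= 1, got {self.age_days}")
        if not self.sl_mm > 0:
            out.append(f"sl_mm must be > 0, got {self.sl_mm}")
        if not self.dw_mg > 0:
            out.append(f"dw_mg must be > 0, got {self.dw_mg}")
        if not self.cn > 0:
            out.append(f"cn must be > 0, got {self.cn}")
        if self.stage not in STAGES:
            out.append(f"stage must be one of {STAGES}, got {self.stage!r}")
        return out

    def warnings(self) -> list[str]:
        """Plausibility warnings that do not reject the record."""
        if self.d13c >= 0:
            return [f"d13c >= 0 (got {self.d13c}); marine tissue is normally negative"]
        return []


@dataclass
class StationRecord:
    """Hydrography and zooplankton isotopic baselines for one station."""

    station_id: str
    cohort: str
    temp_c: float
    sal_psu: float
    d15n_micro: float
    d13c_micro: float
    d15n_meso: float
    d13c_meso: float
    cn_micro: Optional[float] = None
    cn_meso: Optional[float] = None
    d13c_corrected: bool = False

    def problems(self) -> list[str]:
        out = []
        for name in ("d15n_micro", "d13c_micro", "d15n_meso", "d13c_meso"):
            v = getattr(self, name)
            if v is None or not math.isfinite(v):
                out.append(f"{name} must be finite, got {v}")
        return out


@dataclass
class CohortDataset:
    """All larvae and stations of one run, plus free-text provenance."""

    larvae: list[LarvaRecord] = field(default_factory=list)
    stations: list[StationRecord] = field(default_factory=list)
    provenance: str = ""

    def station_lookup(self) -> dict[tuple[str, str], StationRecord]:
        return {(s.cohort, s.station_id): s for s in self.stations}

    def cohorts(self) -> list[str]:
        seen: dict[str, None] = {}
        for l in self.larvae:
            seen.setdefault(l.cohort)
        return list(seen)

    def subset(self, cohort: str | None = None, stage: str | None = None) -> "CohortDataset":
        larvae = [
            l
            for l in self.larvae
            if (cohort is None or l.cohort == cohort) and (stage is None or l.stage == stage)
        ]
        stations = [s for s in self.stations if cohort is None or s.cohort == cohort]
        return CohortDataset(larvae=larvae, stations=stations, provenance=self.provenance)


@dataclass
class ValidationReport:
    """Report-only dataset diagnostics; the dataset is never mutated."""

    unresolved_stations: list[str] = field(default_factory=list)
    duplicate_ids: list[str] = field(default_factory=list)
    range_violations: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def is_clean(self) -> bool:
        return not (self.unresolved_stations or self.duplicate_ids or self.range_violations)


# Default input column names; keys are LarvaRecord field names.
DEFAULT_LARVA_SCHEMA = {
    "larva_id": "larva_id",
    "cohort": "cohort",
    "station_id": "station_id",
    "age_days": "AGE",
    "sl_mm": "SL",
    "dw_mg": "DW",
    "radius_um": "RADIUS",
    "miw_um": "MIW",
    "stage": "stage",
    "d15n": "d15N",
    "d13c": "d13C",
    "cn": "CN",
}

DEFAULT_STATION_SCHEMA = {
    "station_id": "station_id",
    "cohort": "cohort",
    "temp_c": "TEMP",
    "sal_psu": "SAL",
    "d15n_micro": "d15N_micro",
    "d13c_micro": "d13C_micro",
    "d15n_meso": "d15N_meso",
    "d13c_meso": "d13C_meso",
}

_OPTIONAL_STATION_COLUMNS = {"cn_micro": "CN_micro", "cn_meso": "CN_meso"}


def _coerce(value: Any, typ: str) -> Any:
    if typ == "int":
        f = float(value)
        if not f.is_integer():
            raise ValueError(f"expected integer, got {value}")
        return int(f)
    if typ == "float":
        return float(value)
    if typ == "bool":
        if isinstance(value, bool):
            return value
        return str(value).strip().lower() in ("true", "1", "yes")
    return str(value)


_FIELD_TYPES = {int: "int", float: "float", bool: "bool", str: "str"}


def _resolve_schema(schema: dict[str, str], columns, path) -> dict[str, str]:
    """Map record fields to file columns.

    Accepts either the configured column name or the record field name
    itself (files written by :func:`write_table` use field names).
    """
    resolved = {}
    missing = []
    for fname, col in schema.items():
        if col in columns:
            resolved[fname] = col
        elif fname in columns:
            resolved[fname] = fname
        else:
            missing.append(col)
    if missing:
        raise SchemaError(f"missing columns in {path}: {missing}")
    return resolved


def read_larvae(
    path: str | Path, schema: dict[str, str] | None = None
) -> tuple[list[LarvaRecord], list[tuple[int, str]]]:
    """Read larvae from CSV.

    Returns ``(records, rejected)`` where ``rejected`` lists
    ``(row_number, reason)`` for rows that fail parsing or record invariants
    (row numbers are 1-based data rows, header excluded).  A missing column
    raises :class:`SchemaError`.
    """
    schema = {**DEFAULT_LARVA_SCHEMA, **(schema or {})}
    df = pd.read_csv(path, float_precision="round_trip")
    schema = _resolve_schema(schema, df.columns, path)

    types = {"age_days": "int", "stage": "str"}
    records: list[LarvaRecord] = []
    rejected: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rowd = dict(zip(df.columns, row))
        kwargs = {}
        try:
            for fname, col in schema.items():
                typ = types.get(fname, "float" if fname not in ("larva_id", "cohort", "station_id") else "str")
                kwargs[fname] = _coerce(rowd[col], typ)
        except (ValueError, TypeError) as exc:
            rejected.append((i, f"unparseable value: {exc}"))
            continue
        rec = LarvaRecord(**kwargs)
        probs = rec.problems()
        if probs:
            rejected.append((i, "; ".join(probs)))
        else:
            records.append(rec)
    return records, rejected


def read_stations(
    path: str | Path, schema: dict[str, str] | None = None
) -> tuple[list[StationRecord], list[tuple[int, str]]]:
    """Read station baselines from CSV; same contract as :func:`read_larvae`."""
    schema = {**DEFAULT_STATION_SCHEMA, **(schema or {})}
    df = pd.read_csv(path, float_precision="round_trip")
    schema = _resolve_schema(schema, df.columns, path)

    records: list[StationRecord] = []
    rejected: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rowd = dict(zip(df.columns, row))
        kwargs: dict[str, Any] = {}
        try:
            for fname, col in schema.items():
                typ = "str" if fname in ("station_id", "cohort") else "float"
                kwargs[fname] = _coerce(rowd[col], typ)
            for fname, col in _OPTIONAL_STATION_COLUMNS.items():
                if col in df.columns and pd.notna(rowd[col]):
                    kwargs[fname] = float(rowd[col])
        except (ValueError, TypeError) as exc:
            rejected.append((i, f"unparseable value: {exc}"))
            continue
        rec = StationRecord(**kwargs)
        probs = rec.problems()
        if probs:
            rejected.append((i, "; ".join(probs)))
        else:
            records.append(rec)
    return records, rejected


def validate_dataset(dataset: CohortDataset) -> ValidationReport:
    """Cross-record consistency checks.  Pure: the dataset is not modified."""
    report = ValidationReport()
    lookup = dataset.station_lookup()
    if len(lookup) != len(dataset.stations):
        keys = [(s.cohort, s.station_id) for s in dataset.stations]
        dups = sorted({k for k in keys if keys.count(k) > 1})
        report.range_violations.extend(f"duplicate station record {k}" for k in dups)

    seen_ids: set[str] = set()
    for larva in dataset.larvae:
        if larva.larva_id in seen_ids:
            report.duplicate_ids.append(larva.larva_id)
        seen_ids.add(larva.larva_id)
        if (larva.cohort, larva.station_id) not in lookup:
            report.unresolved_stations.append(
                f"{larva.larva_id}: no station ({larva.cohort}, {larva.station_id})"
            )
        probs = larva.problems()
        if probs:
            report.range_violations.append(f"{larva.larva_id}: " + "; ".join(probs))
        report.warnings.extend(f"{larva.larva_id}: {w}" for w in larva.warnings())
    return report


def write_table(records: Sequence[Any], path: str | Path) -> pd.DataFrame:
    """Write a sequence of dataclass records (or a DataFrame) to CSV.

    Column order follows dataclass field order; floats are written at full
    round-trip precision so ``read(write(x)) == x`` exactly.
    """
    if isinstance(records, pd.DataFrame):
        if records.empty:
            raise ValueError("refusing to write an empty table")
        df = records
    else:
        records = list(records)
        if not records:
            raise ValueError("refusing to write an empty table")
        df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            # shortest round-trip repr so read(write(x)) == x bit-exactly
            out[col] = out[col].map(lambda v: "" if pd.isna(v) else repr(float(v)))
    out.to_csv(path, index=False)
    return df


def read_records(path: str | Path, cls: type) -> list[Any]:
    """Read back a CSV written by :func:`write_table` into dataclass ``cls``."""
    df = pd.read_csv(path, float_precision="round_trip")
    fields = dataclasses.fields(cls)
    out = []
    for row in df.itertuples(index=False):
        rowd = dict(zip(df.columns, row))
        kwargs = {}
        for f in fields:
            if f.name not in rowd:
                continue
            v = rowd[f.name]
            if v is None or (isinstance(v, float) and math.isnan(v)):
                kwargs[f.name] = None
                continue
            typ = _FIELD_TYPES.get(f.type if isinstance(f.type, type) else None)
            if typ is None:
                tname = str(f.type)
                if "int" in tname:
                    typ = "int"
                elif "bool" in tname:
                    typ = "bool"
                elif "float" in tname:
                    typ = "float"
                else:
                    typ = "str"
            kwargs[f.name] = _coerce(v, typ)
        out.append(cls(**kwargs))
    return out


def load_config_yaml(path: str | Path) -> dict:
    """Load a YAML run-configuration file into a plain dict."""
    with open(path, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh) or {}
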