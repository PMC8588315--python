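"""Readers and writers for the delimited-table formats used by the pipeline.

Formats
-------
Activity tables
    Long-format CSV/TSV with columns ``dose,day,biostimulant,replicate,value``
    (UTF-8, '.' decimal separator); one file per response.  Rows sharing a
    treatment key are gathered as replicates in file order.
Colony series
    CSV with columns ``group,dose,day,biostimulant,replicate,day1..day10``;
    the day columns are daily increments of newly appeared colonies.
OTU tables
    TSV with ``otu_id``, ``lineage`` (semicolon-separated, rank-prefixed:
    ``p__X;c__Y;o__Z;f__W;g__V``), then one column per sample.
Sample map
    CSV ``sample,dose,day,biostimulant`` linking OTU-table samples to
    treatment cells.
Residue tables
    CSV ``dose,day,residue``.

Parsing never silently drops rows: every row either becomes a record or
raises an error naming the row.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError, ValidationError
from .model import (
    RANKS,
    ActivityTable,
    ColonyEmergenceSeries,
    OtuTable,
    ResidueSeries,
    TreatmentKey,
)

_RANK_PREFIXES = ("p__", "c__", "o__", "f__", "g__")

_TRUE = {"true", "1", "yes", "pc", "y", "t"}
_FALSE = {"false", "0", "no", "none", "n", "f"}


def _sep_for(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def _parse_bool(raw: object, row: int, column: str) -> bool:
    text = str(raw).strip().lower()
    if text in _TRUE:
        return True
    if text in _FALSE:
        return False
    raise ParseError(f"row {row}: cannot parse {column}={raw!r} as a boolean")


def _parse_float(raw: object, row: int, column: str) -> float:
    try:
        return float(raw)
    except (TypeError, ValueError):
        raise ParseError(f"row {row}: cannot parse {column}={raw!r} as a number") from None


def _parse_int(raw: object, row: int, column: str) -> int:
    value = _parse_float(raw, row, column)
    if value != int(value):
        raise ParseError(f"row {row}: {column}={raw!r} is not an integer")
    return int(value)


def _require_columns(frame: pd.DataFrame, required: Sequence[str], path: Path) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


# ---------------------------------------------------------------------------
# activity tables


def read_activity_table(
    path: str | Path,
    response_name: str = "",
    unit: str = "",
    sep: str | None = None,
) -> ActivityTable:
    """Read a long-format activity table.

    Raises
    ------
    SchemaError
        if a required column is absent.
    ParseError
        if a cell is non-numeric (message names the row).
    ValidationError
        if a value is negative.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep=_sep_for(path, sep), dtype=str, keep_default_na=False)
    _require_columns(frame, ("dose", "day", "biostimulant", "replicate", "value"), path)
    table = ActivityTable(response_name=response_name or path.stem, unit=unit)
    for i, row in enumerate(frame.itertuples(index=False), start=2):  # header is row 1
        key = TreatmentKey(
            dose=_parse_float(row.dose, i, "dose"),
            time_day=_parse_int(row.day, i, "day"),
            biostimulant=_parse_bool(row.biostimulant, i, "biostimulant"),
        )
        value = _parse_float(row.value, i, "value")
        if value < 0:
            raise ValidationError(f"{path} row {i}: negative value {value}")
        table.add(key, value)
    return table


def write_activity_table(table: ActivityTable, path: str | Path, sep: str | None = None) -> None:
    path = Path(path)
    rows = []
    for key in sorted(table.records):
        for replicate, value in enumerate(table.records[key], start=1):
            rows.append(
                {
                    "dose": key.dose,
                    "day": key.time_day,
                    "biostimulant": key.biostimulant,
                    "replicate": replicate,
                    "value": repr(value),
                }
            )
    pd.DataFrame(rows, columns=["dose", "day", "biostimulant", "replicate", "value"]).to_csv(
        path, sep=_sep_for(path, sep), index=False
    )


# ---------------------------------------------------------------------------
# colony emergence series


def read_colony_series(path: str | Path, sep: str | None = None) -> list[ColonyEmergenceSeries]:
    path = Path(path)
    frame = pd.read_csv(path, sep=_sep_for(path, sep), dtype=str, keep_default_na=False)
    day_cols = [f"day{i}" for i in range(1, 11)]
    _require_columns(frame, ["group", "dose", "day", "biostimulant", "replicate", *day_cols], path)
    out: list[ColonyEmergenceSeries] = []
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        key = TreatmentKey(
            dose=_parse_float(row.dose, i, "dose"),
            time_day=_parse_int(row.day, i, "day"),
            biostimulant=_parse_bool(row.biostimulant, i, "biostimulant"),
        )
        counts = tuple(_parse_int(getattr(row, c), i, c) for c in day_cols)
        out.append(
            ColonyEmergenceSeries(
                group_name=str(row.group),
                treatment=key,
                replicate=_parse_int(row.replicate, i, "replicate"),
                counts=counts,
            )
        )
    return out


def write_colony_series(
    series: Iterable[ColonyEmergenceSeries], path: str | Path, sep: str | None = None
) -> None:
    path = Path(path)
    day_cols = [f"day{i}" for i in range(1, 11)]
    rows = []
    for s in series:
        row = {
            "group": s.group_name,
            "dose": s.treatment.dose,
            "day": s.treatment.time_day,
            "biostimulant": s.treatment.biostimulant,
            "replicate": s.replicate,
        }
        row.update(dict(zip(day_cols, s.counts)))
        rows.append(row)
    pd.DataFrame(rows, columns=["group", "dose", "day", "biostimulant", "replicate", *day_cols]).to_csv(
        path, sep=_sep_for(path, sep), index=False
    )


# ---------------------------------------------------------------------------
# OTU tables


def parse_lineage(text: str) -> tuple[str, ...]:
    """Split a rank-prefixed lineage string into 5 ordered slots.

    ``"p__Proteobacteria;c__Alphaproteobacteria"`` becomes
    ``("Proteobacteria", "Alphaproteobacteria", "", "", "")``.  Prefixes are
    optional; missing trailing ranks become empty slots.
    """
    parts = [p.strip() for p in str(text).split(";")] if str(text).strip() else []
    if len(parts) > len(RANKS):
        raise ValidationError(f"lineage {text!r} has more than {len(RANKS)} ranks")
    slots = []
    for j, part in enumerate(parts):
        for prefix in _RANK_PREFIXES:
            if part.startswith(prefix):
                part = part[len(prefix):]
                break
        slots.append(part)
    slots.extend("" for _ in range(len(RANKS) - len(slots)))
    return tuple(slots)


def format_lineage(slots: Sequence[str]) -> str:
    return ";".join(f"{p}{s}" for p, s in zip(_RANK_PREFIXES, slots))


def read_otu_table(path: str | Path, sep: str | None = None) -> OtuTable:
    """Read a lineage-annotated wide OTU count matrix (TSV by default)."""
    path = Path(path)
    frame = pd.read_csv(path, sep=_sep_for(path, sep), dtype=str, keep_default_na=False)
    _require_columns(frame, ("otu_id", "lineage"), path)
    samples = [c for c in frame.columns if c not in ("otu_id", "lineage")]
    otu_ids = [str(x) for x in frame["otu_id"]]
    lineages = [parse_lineage(x) for x in frame["lineage"]]
    counts = np.empty((len(otu_ids), len(samples)), dtype=np.int64)
    col_index = {s: frame.columns.get_loc(s) for s in samples}
    for r in range(len(frame)):
        for c, sample in enumerate(samples):
            raw = frame.iat[r, col_index[sample]]
            value = _parse_float(raw, r + 2, sample)
            if value < 0 or value != int(value):
                raise ValidationError(f"{path} row {r + 2}: count {raw!r} must be a non-negative integer")
            counts[r, c] = int(value)
    return OtuTable(otu_ids=otu_ids, lineages=lineages, samples=samples, counts=counts)


def write_otu_table(table: OtuTable, path: str | Path, sep: str | None = None) -> None:
    path = Path(path)
    frame = pd.DataFrame(table.counts, columns=table.samples)
    frame.insert(0, "lineage", [format_lineage(lin) for lin in table.lineages])
    frame.insert(0, "otu_id", table.otu_ids)
    frame.to_csv(path, sep="\t" if sep is None else sep, index=False)


# ---------------------------------------------------------------------------
# sample map and residue tables


def read_sample_map(path: str | Path) -> dict[str, TreatmentKey]:
    path = Path(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(frame, ("sample", "dose", "day", "biostimulant"), path)
    mapping: dict[str, TreatmentKey] = {}
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        sample = str(row.sample)
        if sample in mapping:
            raise ValidationError(f"{path} row {i}: duplicate sample {sample!r}")
        mapping[sample] = TreatmentKey(
            dose=_parse_float(row.dose, i, "dose"),
            time_day=_parse_int(row.day, i, "day"),
            biostimulant=_parse_bool(row.biostimulant, i, "biostimulant"),
        )
    return mapping


def write_sample_map(mapping: dict[str, TreatmentKey], path: str | Path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(["sample", "dose", "day", "biostimulant"])
        for sample, key in mapping.items():
            writer.writerow([sample, key.dose, key.time_day, key.biostimulant])


def read_residue_table(path: str | Path) -> list[ResidueSeries]:
    path = Path(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(frame, ("dose", "day", "residue"), path)
    by_dose: dict[float, dict[int, float]] = {}
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        dose = _parse_float(row.dose, i, "dose")
        by_dose.setdefault(dose, {})[_parse_int(row.day, i, "day")] = _parse_float(
            row.residue, i, "residue"
        )
    return [ResidueSeries(dose=d, observations=obs) for d, obs in sorted(by_dose.items())]


def write_residue_table(series: Iterable[ResidueSeries], path: str | Path) -> None:
    rows = []
    for s in series:
        for day in sorted(s.observations):
            rows.append({"dose": s.dose, "day": day, "residue": repr(s.observations[day])})
    pd.DataFrame(rows, columns=["dose", "day", "residue"]).to_csv(path, index=False)
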