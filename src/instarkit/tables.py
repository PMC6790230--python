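"""Reading, writing, cleaning and summarizing morphometric tables.

The package bundles two fixtures digitized from published measurement
tables of fossil *Mycetobia* larvae and pupae preserved in Baltic and
Bitterfeld amber: ``"larvae"`` (36 larval records) and ``"pupae"``
(54 pupal part measurements covering 18 pupae).  Fixtures are stored
verbatim as printed, including one manifestly typographic body-length
cell, which is handled by :func:`clean_larval_table` rather than edited.
"""
from __future__ import annotations

import csv
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .errors import EmptySummaryError, TableParseError
from .records import (
    LARVAL_VARIABLES,
    CleaningReport,
    LarvalRecord,
    PupalRecord,
    RangeSummary,
    round_half_away,
)

__all__ = [
    "FIXTURES",
    "load_larval_table",
    "load_pupal_table",
    "write_larval_table",
    "write_pupal_table",
    "clean_larval_table",
    "summarize_range",
]

#: bundled fixture names -> packaged CSV resources
FIXTURES = {
    "larvae": "larvae_table2.csv",
    "pupae": "pupae_table3.csv",
}

LARVAL_COLUMNS = (
    "specimen_id",
    "piece_index",
    "total_length_um",
    "head_length_um",
    "head_width_um",
    "stage_label",
    "source",
)
PUPAL_COLUMNS = ("specimen_id", "piece_index", "morphotype", "part", "length_um")

_MISSING = {"", "na", "n/a", "nan", "none"}

#: printed part names -> canonical names
_PART_ALIASES = {
    "abdomen": "abdomen",
    "head_thorax": "head_thorax",
    "thorax+head": "head_thorax",
    "head+thorax": "head_thorax",
    "thorax_head": "head_thorax",
    "total": "total",
}


def _is_missing(cell: Optional[str]) -> bool:
    return cell is None or cell.strip().lower() in _MISSING


def _parse_float(cell: str, row: int, column: str) -> Optional[float]:
    if _is_missing(cell):
        return None
    try:
        return float(cell)
    except ValueError:
        raise TableParseError(
            f"non-numeric measurement {cell!r}", row=row, column=column
        ) from None


def _parse_int(cell: str, row: int, column: str) -> Optional[int]:
    if _is_missing(cell):
        return None
    try:
        return int(cell)
    except ValueError:
        raise TableParseError(f"non-integer value {cell!r}", row=row, column=column) from None


def _open_source(source: Union[str, Path], fixtures: dict):
    """Resolve a path or bundled fixture name to text lines + a label."""
    name = str(source)
    if name in fixtures:
        text = (
            resources.files("instarkit.data").joinpath(fixtures[name]).read_text("utf-8")
        )
        return text.splitlines(), name
    path = Path(source)
    if not path.exists():
        raise TableParseError(
            f"source {name!r} is neither a readable file nor one of the bundled "
            f"fixtures {sorted(fixtures)}"
        )
    return path.read_text("utf-8").splitlines(), path.name


def _reader(lines: Sequence[str], mandatory: Sequence[str], label: str):
    reader = csv.DictReader(lines)
    header = reader.fieldnames or []
    missing = [c for c in mandatory if c not in header]
    if missing:
        raise TableParseError(
            f"{label}: missing mandatory columns {missing}; found {header}"
        )
    return reader


def load_larval_table(source: Union[str, Path]) -> list[LarvalRecord]:
    """Load larval records from a CSV file or a bundled fixture name.

    Empty and ``NA`` cells become missing values; measurements stay in µm
    as printed.  Raises :class:`TableParseError` naming the offending row
    and column on malformed input.
    """
    lines, label = _open_source(source, {"larvae": FIXTURES["larvae"]})
    mandatory = ("specimen_id", "total_length_um", "head_length_um", "head_width_um")
    records: list[LarvalRecord] = []
    seen: set[tuple] = set()
    for i, row in enumerate(_reader(lines, mandatory, label), start=2):
        sid = (row.get("specimen_id") or "").strip()
        if not sid:
            raise TableParseError("empty specimen_id", row=i, column="specimen_id")
        rec = LarvalRecord(
            specimen_id=sid,
            piece_index=_parse_int(row.get("piece_index", ""), i, "piece_index"),
            total_length=_parse_float(row.get("total_length_um", ""), i, "total_length_um"),
            head_length=_parse_float(row.get("head_length_um", ""), i, "head_length_um"),
            head_width=_parse_float(row.get("head_width_um", ""), i, "head_width_um"),
            stage_label=_parse_int(row.get("stage_label", ""), i, "stage_label"),
            source=(row.get("source") or "").strip() or label,
        )
        if rec.key in seen:
            raise TableParseError(
                f"duplicate (specimen_id, piece_index) {rec.key}", row=i
            )
        seen.add(rec.key)
        records.append(rec)
    return records


def load_pupal_table(source: Union[str, Path]) -> list[PupalRecord]:
    """Load pupal part measurements from a CSV file or the bundled fixture.

    Morphotype cells accept both plain integers and the printed
    ``"morphotype N"`` strings; part names are normalized (e.g.
    ``"thorax+head"`` -> ``"head_thorax"``).
    """
    lines, label = _open_source(source, {"pupae": FIXTURES["pupae"]})
    records: list[PupalRecord] = []
    seen: set[tuple] = set()
    for i, row in enumerate(_reader(lines, ("specimen_id", "morphotype", "part", "length_um"), label), start=2):
        raw_morph = (row.get("morphotype") or "").strip().lower()
        if raw_morph.startswith("morphotype"):
            raw_morph = raw_morph[len("morphotype"):].strip()
        try:
            morphotype = int(raw_morph)
        except ValueError:
            raise TableParseError(
                f"unknown morphotype {row.get('morphotype')!r}", row=i, column="morphotype"
            ) from None
        raw_part = (row.get("part") or "").strip().lower()
        part = _PART_ALIASES.get(raw_part)
        if part is None:
            raise TableParseError(f"unknown part {row.get('part')!r}", row=i, column="part")
        length = _parse_float(row.get("length_um", ""), i, "length_um")
        if length is None:
            raise TableParseError("missing length", row=i, column="length_um")
        rec = PupalRecord(
            specimen_id=(row.get("specimen_id") or "").strip(),
            piece_index=_parse_int(row.get("piece_index", ""), i, "piece_index"),
            morphotype=morphotype,
            part=part,
            length=length,
        )
        dup_key = (rec.specimen_id, rec.piece_index, rec.part)
        if dup_key in seen:
            raise TableParseError(f"duplicate part measurement {dup_key}", row=i)
        seen.add(dup_key)
        records.append(rec)
    return records


def _fmt(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, float):
        return format(value, ".12g")  # full printed precision, no trailing zeros
    return str(value)


def write_larval_table(records: Iterable[LarvalRecord], path: Union[str, Path]) -> None:
    """Write larval records to CSV; a read-back reproduces values exactly."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(LARVAL_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.specimen_id,
                    "" if r.piece_index is None else r.piece_index,
                    _fmt(r.total_length),
                    _fmt(r.head_length),
                    _fmt(r.head_width),
                    _fmt(r.stage_label),
                    r.source,
                ]
            )


def write_pupal_table(records: Iterable[PupalRecord], path: Union[str, Path]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(PUPAL_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.specimen_id,
                    "" if r.piece_index is None else r.piece_index,
                    r.morphotype,
                    r.part,
                    _fmt(r.length),
                ]
            )


def clean_larval_table(
    records: Sequence[LarvalRecord],
) -> tuple[list[LarvalRecord], CleaningReport]:
    """Flag implausible total lengths; never delete anything.

    A body length shorter than the same larva's head capsule is physically
    impossible, so ``total_length < head_length`` (both present) marks the
    total length implausible.  The head measurements of a flagged record
    stay usable.  Cleaning is idempotent and never raises.
    """
    report = CleaningReport(n_input=len(records))
    for rec in records:
        if (
            rec.total_length is not None
            and rec.head_length is not None
            and rec.total_length < rec.head_length
        ):
            rec.flagged_fields.add("total_length")
            report.flags.append(
                (
                    rec.key,
                    "total_length < head_length",
                    {"total_length": rec.total_length, "head_length": rec.head_length},
                )
            )
    return list(records), report


def summarize_range(
    records: Sequence[LarvalRecord] | Sequence[PupalRecord],
    variable: str,
    unit: str = "um",
    rounding: Optional[int] = None,
    morphotype: Optional[int] = None,
) -> RangeSummary:
    """Min/max of one variable over non-missing, non-flagged values.

    For larval records *variable* is one of ``total_length``,
    ``head_length`` or ``head_width``; for pupal records it is a part
    name (``abdomen``, ``head_thorax``, ``total``), optionally restricted
    to one morphotype.  ``unit="mm"`` divides by 1000; *rounding* applies
    half-away-from-zero at the given number of decimals.
    """
    values: list[float] = []
    for rec in records:
        if isinstance(rec, LarvalRecord):
            if variable not in LARVAL_VARIABLES:
                raise ValueError(f"unknown larval variable {variable!r}")
            v = rec.value(variable)
        else:
            if rec.part != variable:
                continue
            if morphotype is not None and rec.morphotype != morphotype:
                continue
            v = rec.length
        if v is not None:
            values.append(v)
    if not values:
        raise EmptySummaryError(f"no usable values for {variable!r}")
    lo, hi = min(values), max(values)
    if unit == "mm":
        lo, hi = lo / 1000.0, hi / 1000.0
    elif unit != "um":
        raise ValueError(f"unit must be 'um' or 'mm', got {unit!r}")
    if rounding is not None:
        lo = round_half_away(lo, rounding)
        hi = round_half_away(hi, rounding)
    return RangeSummary(
        variable=variable, n=len(values), minimum=lo, maximum=hi, unit=unit, rounding=rounding
    )
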