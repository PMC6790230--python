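"""Domain records for larval and pupal morphometry.

All linear measurements are stored in micrometres (µm), the unit of the
source measurements; conversion to mm happens only at reporting time.
Missingness is per field: a larva may have a usable head width while its
head length is unmeasurable.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "LarvalRecord",
    "PupalRecord",
    "CleaningReport",
    "RangeSummary",
    "PUPAL_PARTS",
    "LARVAL_VARIABLES",
]

#: canonical pupal part names; aliases are normalized on load
PUPAL_PARTS = ("abdomen", "head_thorax", "total")

#: measurable larval variables
LARVAL_VARIABLES = ("total_length", "head_length", "head_width")


def _check_positive(name: str, value: Optional[float]) -> None:
    if value is not None and not value > 0:
        raise ValueError(f"{name} must be strictly positive, got {value}")


@dataclass
class LarvalRecord:
    """One measured larva.

    Parameters
    ----------
    specimen_id : str
        Collection accession (e.g. ``"PED-4748"``).
    piece_index : int, optional
        Distinguishes multiple larvae preserved in the same amber piece.
    total_length, head_length, head_width : float, optional
        Measurements in µm; ``None`` marks a missing value.
    stage_label : int, optional
        Instar assignment carried by the source table (1 = youngest).
    source : str
        Fixture or file name the record came from.
    flagged_fields : set of str
        Fields marked implausible by cleaning; excluded from statistics
        but never deleted.
    """

    specimen_id: str
    piece_index: Optional[int] = None
    total_length: Optional[float] = None
    head_length: Optional[float] = None
    head_width: Optional[float] = None
    stage_label: Optional[int] = None
    source: str = ""
    flagged_fields: set = field(default_factory=set)
    inferred_stage: Optional[int] = None

    def __post_init__(self):
        for name in LARVAL_VARIABLES:
            _check_positive(name, getattr(self, name))
        if self.stage_label is not None and self.stage_label < 1:
            raise ValueError(f"stage_label must be >= 1, got {self.stage_label}")

    @property
    def key(self) -> tuple:
        return (self.specimen_id, self.piece_index)

    def value(self, variable: str, *, include_flagged: bool = False) -> Optional[float]:
        """Measurement for *variable*, or None if missing or flagged."""
        if variable not in LARVAL_VARIABLES:
            raise ValueError(f"unknown larval variable {variable!r}")
        v = getattr(self, variable)
        if v is None:
            return None
        if variable in self.flagged_fields and not include_flagged:
            return None
        return v


@dataclass
class PupalRecord:
    """One pupal measurement: a (specimen, part) length in µm."""

    specimen_id: str
    morphotype: int
    part: str
    length: float
    piece_index: Optional[int] = None

    def __post_init__(self):
        if self.morphotype not in (1, 2, 3):
            raise ValueError(f"morphotype must be 1, 2 or 3, got {self.morphotype}")
        if self.part not in PUPAL_PARTS:
            raise ValueError(f"part must be one of {PUPAL_PARTS}, got {self.part!r}")
        _check_positive("length", self.length)

    @property
    def key(self) -> tuple:
        return (self.specimen_id, self.piece_index)


@dataclass
class CleaningReport:
    """Outcome of plausibility screening.

    ``flags`` holds one ``(record key, rule, values)`` triple per violation.
    Flagged values are excluded from downstream statistics but remain in
    storage.
    """

    n_input: int
    flags: list = field(default_factory=list)

    @property
    def n_flagged(self) -> int:
        return len(self.flags)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_flagged": self.n_flagged,
            "flags": [
                {"record": list(key), "rule": rule, "values": values}
                for key, rule, values in self.flags
            ],
        }


@dataclass
class RangeSummary:
    """Min/max of one variable on a requested scale."""

    variable: str
    n: int
    minimum: float
    maximum: float
    unit: str = "um"
    rounding: Optional[int] = None

    def __post_init__(self):
        if self.minimum > self.maximum:
            raise ValueError("minimum exceeds maximum")

    def to_dict(self) -> dict:
        return {
            "variable": self.variable,
            "n": self.n,
            "min": self.minimum,
            "max": self.maximum,
            "unit": self.unit,
            "rounding": self.rounding,
        }


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero (2.5 -> 3, -2.5 -> -3).

    Python's built-in ``round`` is banker's rounding; printed morphometric
    ranges use the conventional rule instead.
    """
    factor = 10.0 ** decimals
    scaled = x * factor
    return math.copysign(math.floor(abs(scaled) + 0.5), scaled) / factor
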