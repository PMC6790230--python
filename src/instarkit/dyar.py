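"""Dyar's-rule analysis: log-linear fits of per-stage mean size.

Dyar's rule (Brooks' law in the crustacean literature) states that a
sclerotized structure grows by a near-constant multiplicative factor at
each moult.  If stage means :math:`m_i` follow :math:`m_{i+1} = m_i / r`
for a constant ratio :math:`r`, then :math:`\\ln m_i` is linear in the
stage index *i*; high :math:`R^2` of that line supports a complete stage
series, and a conspicuously oversized log-increment suggests a missing
stage.

Two line estimators are provided: the Theil–Sen single-median fit (slope =
median of all pairwise slopes, intercept = median of the per-point
intercepts, the convention of R's ``mblm`` single-median method) and
ordinary least squares as a cross-check.  On well-behaved stage means the
two agree closely.
"""
from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .errors import InsufficientDataError, ValidationError
from .records import LarvalRecord

__all__ = [
    "StageSummary",
    "DyarFit",
    "BrooksRatios",
    "MissingStageReport",
    "stage_summaries",
    "theil_sen_fit",
    "ols_fit",
    "brooks_ratios",
    "missing_stage_check",
    "dyar_report",
]


@dataclass
class StageSummary:
    """Descriptive statistics of one size cohort (instar)."""

    stage: int
    n: int
    mean: float
    sd: Optional[float]  # None when n == 1
    minimum: float
    maximum: float

    @property
    def single_specimen(self) -> bool:
        return self.n == 1

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "n": self.n,
            "mean": self.mean,
            "sd": self.sd,
            "min": self.minimum,
            "max": self.maximum,
            "single_specimen": self.single_specimen,
        }


@dataclass
class DyarFit:
    """A fitted line through (stage index, ln mean size) points."""

    method: str  # "theil_sen" | "ols"
    slope: float
    intercept: float
    x: np.ndarray
    y: np.ndarray

    @property
    def fitted(self) -> np.ndarray:
        return self.intercept + self.slope * self.x

    @property
    def residuals(self) -> np.ndarray:
        return self.y - self.fitted

    @property
    def r_squared(self) -> float:
        ss_res = float(np.sum(self.residuals**2))
        ss_tot = float(np.sum((self.y - self.y.mean()) ** 2))
        if ss_tot == 0.0:
            return 1.0 if ss_res == 0.0 else 0.0
        return 1.0 - ss_res / ss_tot

    @property
    def growth_ratio(self) -> float:
        """Implied per-stage Dyar ratio m_i / m_{i+1} = exp(-slope)."""
        return float(np.exp(-self.slope))

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "points": [[float(a), float(b)] for a, b in zip(self.x, self.y)],
            "fitted": self.fitted.tolist(),
            "residuals": self.residuals.tolist(),
        }


@dataclass
class BrooksRatios:
    """Successive stage-mean ratios r_i = m_i / m_{i+1} (expected in (0, 1))."""

    ratios: np.ndarray

    @property
    def growth_factors(self) -> np.ndarray:
        return 1.0 / self.ratios

    @property
    def mean_ratio(self) -> float:
        return float(np.mean(self.ratios))

    @property
    def ratio_range(self) -> tuple[float, float]:
        return float(np.min(self.ratios)), float(np.max(self.ratios))

    @property
    def cv(self) -> float:
        return float(np.std(self.ratios) / np.mean(self.ratios))

    def to_dict(self) -> dict:
        lo, hi = self.ratio_range
        return {
            "ratios": self.ratios.tolist(),
            "growth_factors": self.growth_factors.tolist(),
            "mean_ratio": self.mean_ratio,
            "ratio_range": [lo, hi],
            "cv": self.cv,
        }


@dataclass
class MissingStageReport:
    """Screen for an absent size cohort via oversized log-increments."""

    increments: np.ndarray
    flagged_after: list = field(default_factory=list)
    threshold_multiplier: float = 1.5

    @property
    def verdict(self) -> str:
        return "complete" if not self.flagged_after else "possibly-missing-stage"

    def to_dict(self) -> dict:
        return {
            "increments": self.increments.tolist(),
            "flagged_after_stage": list(map(int, self.flagged_after)),
            "threshold_multiplier": self.threshold_multiplier,
            "verdict": self.verdict,
        }


def stage_summaries(
    values: Sequence[float], labels: Sequence[int]
) -> list[StageSummary]:
    """Per-stage descriptive statistics on the raw µm scale.

    Stage indices must form a contiguous run (an absent intermediate label
    is an error naming the stage).  A single-specimen stage reports its
    actual value as the "mean" and no standard deviation.
    """
    vals = np.asarray(values, dtype=float)
    labs = np.asarray(labels, dtype=int)
    if vals.shape != labs.shape:
        raise ValidationError("values and labels must have equal length")
    if vals.size == 0:
        raise ValidationError("no labelled values")
    present = sorted(set(labs.tolist()))
    for s in range(present[0], present[-1] + 1):
        if s not in present:
            raise ValidationError(f"stage {s} has no members")
    out = []
    for s in present:
        v = vals[labs == s]
        out.append(
            StageSummary(
                stage=int(s),
                n=int(v.size),
                mean=float(v.mean()),
                sd=float(v.std(ddof=1)) if v.size > 1 else None,
                minimum=float(v.min()),
                maximum=float(v.max()),
            )
        )
    return out


def _median(a: np.ndarray) -> float:
    # numpy's median already averages the central pair for even lengths
    return float(np.median(a))


def theil_sen_fit(points: Sequence[tuple[float, float]]) -> DyarFit:
    """Theil–Sen single-median line fit.

    Slope is the median of all pairwise slopes ``(y_j - y_i)/(x_j - x_i)``
    over i < j; pairs with equal x (undefined slope) are excluded.  The
    intercept is the median of ``y_i - slope * x_i`` over all points.
    R² is computed about the fitted line and, unlike OLS, may be negative
    for adversarial data.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValidationError("points must be (x, y) pairs")
    x, y = pts[:, 0], pts[:, 1]
    if np.unique(x).size < 2:
        raise InsufficientDataError("need >= 2 points with distinct x")
    slopes = [
        (y[j] - y[i]) / (x[j] - x[i])
        for i, j in itertools.combinations(range(len(x)), 2)
        if x[j] != x[i]
    ]
    if not slopes:
        raise InsufficientDataError("all pairwise slopes undefined")
    slope = _median(np.asarray(slopes))
    intercept = _median(y - slope * x)
    return DyarFit(method="theil_sen", slope=slope, intercept=intercept, x=x, y=y)


def ols_fit(points: Sequence[tuple[float, float]]) -> DyarFit:
    """Ordinary least-squares line fit on the same points."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValidationError("points must be (x, y) pairs")
    x, y = pts[:, 0], pts[:, 1]
    if np.unique(x).size < 2:
        raise InsufficientDataError("need >= 2 points with distinct x")
    slope, intercept = np.polyfit(x, y, 1)
    return DyarFit(method="ols", slope=float(slope), intercept=float(intercept), x=x, y=y)


def brooks_ratios(summaries: Sequence[StageSummary]) -> BrooksRatios:
    """Successive-stage mean ratios, smallest stage over the next.

    Under Dyar's rule all ratios equal the growth ratio r; their arithmetic
    mean is the headline statistic, reported with the range and CV so
    departures from constancy stay visible.
    """
    if len(summaries) < 2:
        raise InsufficientDataError("need >= 2 stages for growth ratios")
    means = np.array([s.mean for s in summaries], dtype=float)
    if np.any(means == 0):
        raise ValidationError("zero stage mean")
    return BrooksRatios(ratios=means[:-1] / means[1:])


def missing_stage_check(
    fit: DyarFit, threshold_multiplier: float = 1.5
) -> MissingStageReport:
    """Flag log-mean increments large enough to suggest a skipped cohort.

    An increment greater than ``threshold_multiplier`` times the median
    increment is flagged; a geometric series with one stage removed shows a
    doubled increment, which a multiplier of 1.5 catches.
    """
    if len(fit.x) < 3:
        raise InsufficientDataError("need >= 3 stages for the missing-stage check")
    order = np.argsort(fit.x)
    increments = np.diff(fit.y[order])
    med = _median(increments)
    flagged = [
        int(fit.x[order][i])
        for i, inc in enumerate(increments)
        if inc > threshold_multiplier * med
    ]
    return MissingStageReport(
        increments=increments,
        flagged_after=flagged,
        threshold_multiplier=threshold_multiplier,
    )


def dyar_report(
    records: Sequence[LarvalRecord],
    variable: str = "head_width",
    label_source: str = "paper",
    fit_method: str = "theil_sen",
    threshold_multiplier: float = 3.0,
) -> dict:
    """Full ontogeny analysis of a larval table, as one serializable report.

    ``label_source="paper"`` uses the stage labels carried by the table;
    ``"gaps"`` derives labels from a gap partition of *variable* with the
    given threshold multiplier.  The report bundles stage summaries, both
    line fits, growth ratios, the missing-stage verdict and the implied
    ontogenetic stage sequence.
    """
    from .partition import assign_stage_labels, partition_by_gaps, sorted_gaps

    if label_source == "paper":
        pairs = [
            (r.value(variable), r.stage_label)
            for r in records
            if r.value(variable) is not None and r.stage_label is not None
        ]
    elif label_source == "gaps":
        usable = [r for r in records if r.value(variable) is not None]
        if len(usable) >= 2:
            series = sorted_gaps([r.value(variable) for r in usable], variable=variable)
            part = partition_by_gaps(series, c=threshold_multiplier)
            assign_stage_labels(usable, part, variable)
        pairs = [
            (r.value(variable), r.inferred_stage)
            for r in records
            if r.value(variable) is not None and r.inferred_stage is not None
        ]
    else:
        raise ValidationError(f"label_source must be 'paper' or 'gaps', got {label_source!r}")
    if not pairs:
        raise ValidationError(f"no labelled {variable} values under {label_source!r} labels")

    values = [v for v, _ in pairs]
    labels = [s for _, s in pairs]
    summaries = stage_summaries(values, labels)
    points = [(float(s.stage), float(np.log(s.mean))) for s in summaries]
    fits = {"theil_sen": theil_sen_fit(points), "ols": ols_fit(points)}
    if fit_method not in fits:
        raise ValidationError(f"fit_method must be 'theil_sen' or 'ols', got {fit_method!r}")
    ratios = brooks_ratios(summaries)
    missing = (
        missing_stage_check(fits[fit_method]).to_dict()
        if len(summaries) >= 3
        else None
    )
    return {
        "variable": variable,
        "label_source": label_source,
        "fit_method": fit_method,
        "n_stages": len(summaries),
        "stage_sequence": [s.stage for s in summaries],
        "stages": [s.to_dict() for s in summaries],
        "fits": {name: f.to_dict() for name, f in fits.items()},
        "r_squared": fits[fit_method].r_squared,
        "brooks": ratios.to_dict(),
        "missing_stage": missing,
    }


def report_to_json(report: dict, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(report, indent=2), encoding="utf-8")
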