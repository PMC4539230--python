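"""Discounting-curve data types, value normalization, and the AUC statistic.

The core quantity is the area under the normalized indifference-point curve
(AUC): delays are rescaled to [0, 1] by the longest delay, indifference
values to [0, 1] by the maximum possible value (VAS 100, or the $1000
delayed amount), and the area is the trapezoidal sum over consecutive
points.  AUC of 1 means no discounting; AUC of 0 means the delayed outcome
is worthless at every delay.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "DelaySchedule",
    "IndifferenceCurve",
    "AUCResult",
    "ConsistencyResult",
    "SDT_SCHEDULE",
    "DDT_SCHEDULE",
    "SEXUAL_CONDITIONS",
    "ALL_CONDITIONS",
    "normalize_delays",
    "compute_auc",
    "trapezoid_auc",
    "vas_to_proportion",
    "check_ddt_consistency",
    "write_curves_csv",
    "read_curves_csv",
]

SEXUAL_CONDITIONS = ("least_attractive", "most_attractive", "least_sti", "most_sti")
ALL_CONDITIONS = SEXUAL_CONDITIONS + ("monetary",)

COMMODITIES = ("sexual", "monetary")


class ValidationError(ValueError):
    """Raised when a curve, schedule or response fails validation."""


@dataclass(frozen=True)
class DelaySchedule:
    """An ordered set of delays, as text labels plus durations in hours."""

    labels: tuple[str, ...]
    durations: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.durations):
            raise ValidationError("labels and durations must have equal length")
        if len(self.durations) == 0:
            raise ValidationError("schedule must be non-empty")
        d = np.asarray(self.durations, dtype=float)
        if np.any(d < 0):
            raise ValidationError("durations must be >= 0")
        if np.any(np.diff(d) <= 0):
            raise ValidationError("durations must be strictly increasing")

    def __len__(self) -> int:
        return len(self.durations)


# Delays to condom-protected sex: a zero-delay anchor trial plus seven delays
# out to three months.  Calendar conversions use 1 month = 30 days.
SDT_SCHEDULE = DelaySchedule(
    labels=("now", "1 hour", "3 hours", "6 hours", "1 day", "1 week", "1 month", "3 months"),
    durations=(0.0, 1.0, 3.0, 6.0, 24.0, 168.0, 720.0, 2160.0),
)

# Delays to the $1000 larger-later amount, 1 day out to 5 years (365-day year).
DDT_SCHEDULE = DelaySchedule(
    labels=("1 day", "1 week", "1 month", "3 months", "1 year", "5 years"),
    durations=(24.0, 168.0, 720.0, 2160.0, 8760.0, 43800.0),
)


@dataclass(frozen=True)
class IndifferenceCurve:
    """One participant x one condition's normalized indifference points.

    ``values`` are proportions in [0, 1]: VAS responses divided by 100 for
    sexual curves, indifference amounts divided by the $1000 delayed amount
    for monetary curves.
    """

    participant_id: str
    commodity: str
    condition: str
    schedule: DelaySchedule
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.commodity not in COMMODITIES:
            raise ValidationError(f"unknown commodity {self.commodity!r}")
        if self.condition not in ALL_CONDITIONS:
            raise ValidationError(f"unknown condition {self.condition!r}")
        if (self.condition == "monetary") != (self.commodity == "monetary"):
            raise ValidationError("condition and commodity disagree")
        if len(self.values) != len(self.schedule):
            raise ValidationError("one value per schedule entry required")
        v = np.asarray(self.values, dtype=float)
        if np.any((v < 0) | (v > 1)):
            raise ValidationError("values must lie in [0, 1]")


@dataclass(frozen=True)
class AUCResult:
    participant_id: str
    condition: str
    auc: float


@dataclass(frozen=True)
class ConsistencyResult:
    passed: bool
    reasons: tuple[str, ...]


def normalize_delays(schedule: DelaySchedule) -> np.ndarray:
    """Map a schedule's durations to unit positions in [0, 1].

    Each duration is divided by the maximum duration, so the last position
    is exactly 1 and relative spacing is preserved.
    """
    d = np.asarray(schedule.durations, dtype=float)
    return d / d[-1]


def trapezoid_auc(positions: Sequence[float], values: Sequence[float]) -> float:
    """Trapezoidal area under (positions, values); positions in [0, 1]."""
    x = np.asarray(positions, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValidationError("need at least 2 points to integrate")
    return float(np.trapezoid(y, x))


def compute_auc(curve: IndifferenceCurve, anchor: str = "measured") -> AUCResult:
    """Area under a normalized indifference curve.

    Parameters
    ----------
    curve
        A validated :class:`IndifferenceCurve`.
    anchor
        ``"measured"`` (default) integrates the curve as measured, including
        the zero-delay trial of sexual curves.  ``"exclude-zero"`` drops a
        measured point at position 0 from sexual curves before integrating
        (the zero-delay trial then only defines the origin of the axis, not
        the integrand).  Monetary curves always receive a synthetic anchor
        (0, 1.0): the undelayed full amount is worth its face value by
        definition.
    """
    if anchor not in ("measured", "exclude-zero"):
        raise ValidationError(f"unknown anchor mode {anchor!r}")
    x = normalize_delays(curve.schedule)
    y = np.asarray(curve.values, dtype=float)
    if curve.commodity == "monetary":
        if x[0] > 0:
            x = np.concatenate([[0.0], x])
            y = np.concatenate([[1.0], y])
    elif anchor == "exclude-zero" and x[0] == 0.0:
        x, y = x[1:], y[1:]
        # rescale the remaining positions to span [0, 1] so the AUC of a
        # constant curve still equals the constant
        x = (x - x[0]) / (x[-1] - x[0])
    auc = trapezoid_auc(x, y)
    # guard against float fuzz at the boundaries
    auc = min(1.0, max(0.0, auc))
    return AUCResult(curve.participant_id, curve.condition, auc)


def vas_to_proportion(vas, mode: str = "strict"):
    """Convert visual-analog-scale responses (0-100) to proportions in [0, 1].

    ``strict`` raises on out-of-range input; ``lenient`` clips to [0, 100]
    and logs a warning with the number of clipped responses.
    """
    arr = np.asarray(vas, dtype=float)
    out_of_range = (arr < 0) | (arr > 100)
    n_bad = int(np.count_nonzero(out_of_range))
    if n_bad:
        if mode == "strict":
            raise ValidationError(f"{n_bad} VAS response(s) outside [0, 100]")
        if mode != "lenient":
            raise ValidationError(f"unknown mode {mode!r}")
        logger.warning("clipped %d out-of-range VAS response(s)", n_bad)
        arr = np.clip(arr, 0.0, 100.0)
    result = arr / 100.0
    if np.isscalar(vas) or np.ndim(vas) == 0:
        return float(result)
    return result


# Consistency screen for titrated monetary curves: flag curves whose
# indifference points rise too sharply between adjacent delays, or that show
# no overall decline from the first to the last delay.
DDT_MAX_RISE = 0.20  # fraction of the delayed amount
DDT_MIN_DECLINE = 0.10


def check_ddt_consistency(curve: IndifferenceCurve) -> ConsistencyResult:
    """Systematic-responding screen for a 6-point monetary curve."""
    if curve.commodity != "monetary":
        raise ValidationError("consistency check applies to monetary curves")
    v = np.asarray(curve.values, dtype=float)
    reasons: list[str] = []
    rises = np.diff(v)
    bad = np.nonzero(rises > DDT_MAX_RISE)[0]
    if bad.size:
        delays = [curve.schedule.labels[i + 1] for i in bad]
        reasons.append(
            "indifference point rises by more than "
            f"{DDT_MAX_RISE:.2f} of the delayed amount at: {', '.join(delays)}"
        )
    if v[0] - v[-1] < DDT_MIN_DECLINE:
        reasons.append(
            f"last indifference point is not at least {DDT_MIN_DECLINE:.2f} "
            "below the first (no overall discounting)"
        )
    return ConsistencyResult(passed=not reasons, reasons=tuple(reasons))


# ---------------------------------------------------------------------------
# tidy serialization: participant_id, commodity, condition, delay_hours, value

CURVE_CSV_HEADER = ["participant_id", "commodity", "condition", "delay_hours", "value"]


def write_curves_csv(curves: Iterable[IndifferenceCurve], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CURVE_CSV_HEADER)
        for curve in curves:
            for d, v in zip(curve.schedule.durations, curve.values):
                writer.writerow(
                    [curve.participant_id, curve.commodity, curve.condition, repr(d), repr(v)]
                )


def read_curves_csv(path) -> list[IndifferenceCurve]:
    """Read curves from the tidy layout, grouping rows by (participant, condition)."""
    groups: dict[tuple[str, str, str], list[tuple[float, float]]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(CURVE_CSV_HEADER) - set(reader.fieldnames or ())
        if missing:
            raise ValidationError(f"curve file missing columns: {sorted(missing)}")
        for row in reader:
            key = (row["participant_id"], row["commodity"], row["condition"])
            groups.setdefault(key, []).append((float(row["delay_hours"]), float(row["value"])))
    curves = []
    for (pid, commodity, condition), points in groups.items():
        points.sort(key=lambda p: p[0])
        durations = tuple(p[0] for p in points)
        values = tuple(p[1] for p in points)
        labels = tuple(f"{d:g} h" for d in durations)
        for ref in (SDT_SCHEDULE, DDT_SCHEDULE):
            if durations == ref.durations:
                schedule = ref
                break
        else:
            schedule = DelaySchedule(labels=labels, durations=durations)
        curves.append(IndifferenceCurve(pid, commodity, condition, schedule, values))
    return curves


def hyperbolic_value(amount: float, k, delay_hours) -> np.ndarray:
    """Subjective value A / (1 + k D) of a delayed amount (k in 1/h)."""
    k = np.asarray(k, dtype=float)
    if np.any(k < 0):
        raise ValidationError("discount rate k must be >= 0")
    d = np.asarray(delay_hours, dtype=float)
    return amount / (1.0 + k * d)
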