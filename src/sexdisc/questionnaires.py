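"""Scoring for the four self-report instruments.

HRBS (HIV Risk Taking Behavior Scale): 11 items on 0-5 Likert scales,
scored as the total; higher totals mean riskier behavior.  ZTPI future
subscale: 12 retained items on 1-5 scales, scored as the mean after
reverse-scoring; higher means stronger future orientation.  SSS (Short
Suggestibility Scale): 21 items on 1-5 scales, scored as the total.  CFC
(Consideration of Future Consequences): 12 items on 1-5 scales, mean (or
optionally total) after reverse-scoring.

Reverse-keyed item positions are configurable because published keys vary
by instrument version; the defaults follow the standard keys and the active
key is recorded on every score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "INSTRUMENTS",
    "DEFAULT_REVERSED_ITEMS",
    "ItemResponses",
    "ScaleScore",
    "score_hrbs",
    "score_ztpi_future",
    "score_sss",
    "score_cfc",
    "score_items",
]


@dataclass(frozen=True)
class InstrumentSpec:
    name: str
    n_items: int
    item_min: int
    item_max: int
    aggregate: str  # "sum" or "mean"

    @property
    def scale_range(self) -> tuple[float, float]:
        if self.aggregate == "sum":
            return (self.n_items * self.item_min, self.n_items * self.item_max)
        return (float(self.item_min), float(self.item_max))


INSTRUMENTS: dict[str, InstrumentSpec] = {
    "HRBS": InstrumentSpec("HRBS", 11, 0, 5, "sum"),
    # 13-item future subscale minus the one unrecorded item
    "ZTPI_future": InstrumentSpec("ZTPI_future", 12, 1, 5, "mean"),
    "SSS": InstrumentSpec("SSS", 21, 1, 5, "sum"),
    "CFC": InstrumentSpec("CFC", 12, 1, 5, "mean"),
}

# 1-based positions of reverse-keyed items.  ZTPI positions refer to the
# 12 retained future-subscale items in administration order; CFC uses the
# standard 12-item key.
DEFAULT_REVERSED_ITEMS: dict[str, frozenset[int]] = {
    "HRBS": frozenset(),
    "ZTPI_future": frozenset({2, 6}),
    "SSS": frozenset(),
    "CFC": frozenset({3, 4, 5, 9, 10, 11, 12}),
}


@dataclass(frozen=True)
class ItemResponses:
    instrument: str
    items: tuple[int, ...]

    def __post_init__(self) -> None:
        spec = INSTRUMENTS.get(self.instrument)
        if spec is None:
            raise ValueError(f"unknown instrument {self.instrument!r}")
        if len(self.items) != spec.n_items:
            raise ValueError(
                f"{self.instrument} expects {spec.n_items} items, got {len(self.items)}"
            )
        arr = np.asarray(self.items)
        if np.any((arr < spec.item_min) | (arr > spec.item_max)):
            raise ValueError(
                f"{self.instrument} items must lie in "
                f"[{spec.item_min}, {spec.item_max}]"
            )


@dataclass(frozen=True)
class ScaleScore:
    instrument: str
    score: float
    scale_range: tuple[float, float]
    reversed_items: frozenset[int] = field(default_factory=frozenset)


def score_items(
    responses: ItemResponses,
    reversed_items: frozenset[int] | None = None,
    aggregate: str | None = None,
) -> ScaleScore:
    """Score any instrument: reverse designated items, then sum or average.

    Reversal reflects an item about the scale midpoint:
    r -> (item_min + item_max) - r.
    """
    spec = INSTRUMENTS[responses.instrument]
    if reversed_items is None:
        reversed_items = DEFAULT_REVERSED_ITEMS[responses.instrument]
    bad = [i for i in reversed_items if not 1 <= i <= spec.n_items]
    if bad:
        raise ValueError(f"reversed item positions out of range: {bad}")
    agg = aggregate or spec.aggregate
    items = np.asarray(responses.items, dtype=float)
    reflect = spec.item_min + spec.item_max
    for pos in reversed_items:
        items[pos - 1] = reflect - items[pos - 1]
    score = float(items.sum()) if agg == "sum" else float(items.mean())
    if agg == "sum":
        scale_range = (float(spec.n_items * spec.item_min), float(spec.n_items * spec.item_max))
    else:
        scale_range = (float(spec.item_min), float(spec.item_max))
    return ScaleScore(responses.instrument, score, scale_range, frozenset(reversed_items))


def score_hrbs(items) -> ScaleScore:
    """Total of the 11 HRBS items; range 0-55, higher = riskier."""
    return score_items(ItemResponses("HRBS", tuple(items)))


def score_ztpi_future(items, reversed_items: frozenset[int] | None = None) -> ScaleScore:
    """Mean of the 12 retained future-orientation items; range 1-5."""
    return score_items(ItemResponses("ZTPI_future", tuple(items)), reversed_items)


def score_sss(items) -> ScaleScore:
    """Total of the 21 suggestibility items; range 21-105."""
    return score_items(ItemResponses("SSS", tuple(items)))


def score_cfc(
    items,
    reversed_items: frozenset[int] | None = None,
    aggregate: str = "mean",
) -> ScaleScore:
    """CFC score: mean by default (range 1-5), total by flag (range 12-60)."""
    return score_items(ItemResponses("CFC", tuple(items)), reversed_items, aggregate)
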