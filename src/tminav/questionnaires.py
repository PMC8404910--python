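"""Scoring of the study's questionnaires: SUS, raw NASA-TLX, design Likert scales.

SUS (System Usability Scale): ten items on a 1–5 agreement scale; odd items
contribute ``value − 1``, even items ``5 − value``; the total is scaled by
2.5 to a 0–100 score in 2.5-point increments.

NASA-TLX: six subscales (mental demand, physical demand, temporal demand,
performance, effort, frustration), each 0–100. The overall task load is the
raw (unweighted) arithmetic mean of the six — the common "raw TLX" variant;
the original pairwise-weighting workflow is not implemented.

Design: three five-point Likert scales (visual appeal, intuitiveness,
interaction), summarized per aspect as mean ± sample std.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TLX_SUBSCALES",
    "LIKERT_ASPECTS",
    "SUSResponse",
    "TLXResponse",
    "LikertItem",
    "sus_score",
    "tlx_overall",
    "tlx_from_21_tick",
    "likert_summary",
]

TLX_SUBSCALES = (
    "mental_demand",
    "physical_demand",
    "temporal_demand",
    "performance",
    "effort",
    "frustration",
)

LIKERT_ASPECTS = ("visual_appeal", "intuitiveness", "interaction")


@dataclass(frozen=True)
class SUSResponse:
    """Ten SUS items, each an integer 1 ("Strongly disagree") to 5 ("Strongly agree")."""

    items: tuple[int, ...]

    def __post_init__(self) -> None:
        items = tuple(int(v) for v in self.items)
        if len(items) != 10:
            raise ValueError(f"SUS has exactly 10 items, got {len(items)}")
        if any(v < 1 or v > 5 for v in items):
            raise ValueError("SUS items must be integers in 1..5")
        object.__setattr__(self, "items", items)


@dataclass(frozen=True)
class TLXResponse:
    """Six NASA-TLX subscale ratings, each on 0..100."""

    mental_demand: float
    physical_demand: float
    temporal_demand: float
    performance: float
    effort: float
    frustration: float

    def __post_init__(self) -> None:
        for name in TLX_SUBSCALES:
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"TLX subscale {name} = {v} outside 0..100")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in TLX_SUBSCALES], dtype=float)


@dataclass(frozen=True)
class LikertItem:
    """One design rating: aspect label plus a 1..5 value."""

    aspect: str
    value: int

    def __post_init__(self) -> None:
        if self.aspect not in LIKERT_ASPECTS:
            raise ValueError(f"unknown aspect {self.aspect!r}; expected one of {LIKERT_ASPECTS}")
        if not 1 <= int(self.value) <= 5:
            raise ValueError("Likert value must be in 1..5")


def sus_score(r: SUSResponse | Sequence[int]) -> float:
    """Standard SUS score on 0..100.

    Odd items (1-based) contribute ``value − 1``, even items ``5 − value``;
    the sum of contributions (0..40) is multiplied by 2.5, so achievable
    scores are exactly the multiples of 2.5.
    """
    if not isinstance(r, SUSResponse):
        r = SUSResponse(items=tuple(r))
    total = sum(
        (v - 1) if (i % 2 == 0) else (5 - v)  # i is 0-based: even index = odd item
        for i, v in enumerate(r.items)
    )
    return 2.5 * total


def tlx_overall(r: TLXResponse | Sequence[float]) -> float:
    """Raw-TLX overall task load: unweighted mean of the six subscales."""
    if not isinstance(r, TLXResponse):
        r = TLXResponse(*[float(v) for v in r])
    return float(r.as_array().mean())


def tlx_from_21_tick(value: float) -> float:
    """Rescale a rating from the 21-tick 0..20 paper sheet to the 0..100 scale."""
    if not 0 <= value <= 20:
        raise ValueError("21-tick TLX ratings lie in 0..20")
    return value * 5.0


def likert_summary(items: Iterable[LikertItem]) -> pd.DataFrame:
    """Per-aspect mean ± sample std on the 1..5 scale.

    Aspects are summarized independently; a single rating reports std 0 by
    convention. Returns a DataFrame indexed by aspect with columns
    ``mean``, ``std``, ``n``.
    """
    rows = [(it.aspect, it.value) for it in items]
    if not rows:
        raise ValueError("no Likert items to summarize")
    df = pd.DataFrame(rows, columns=["aspect", "value"])
    out = df.groupby("aspect", sort=True)["value"].agg(["mean", "std", "count"]).rename(columns={"count": "n"})
    out["std"] = out["std"].fillna(0.0)
    return out
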