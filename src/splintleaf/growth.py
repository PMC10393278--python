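"""Growth-rate series and method/treatment error summaries.

Growth is expressed relative to the first monitored day:
value_d = (area_d - area_1) / area_1 x 100 [%].  Error summaries group
signed and absolute percentage measurement errors by any subset of
(method, treatment, illumination) keys, and methods are ranked by mean
absolute error — the statistic that separates splint, stretching, and
manual acquisition in practice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .area import AccuracyRecord

GROUP_KEYS = ("method", "treatment", "illumination")


@dataclass(frozen=True)
class GrowthSeries:
    plant_id: str
    method: str
    treatment: str
    day_index: tuple[int, ...]
    area_mm2: tuple[float, ...]

    def __post_init__(self):
        if len(self.day_index) != len(self.area_mm2):
            raise ValueError("day_index and area_mm2 must have equal length")
        if len(self.day_index) < 2:
            raise ValueError("a growth series needs at least two days")
        if any(b <= a for a, b in zip(self.day_index, self.day_index[1:])):
            raise ValueError("day_index must be strictly increasing")


@dataclass(frozen=True)
class ErrorSummary:
    group: dict
    n: int
    mean_abs_error_pct: float
    mean_signed_error_pct: float
    median_signed_error_pct: float


def growth_rate(series: GrowthSeries) -> np.ndarray:
    """Per-day relative growth (%) against day 1; first entry is 0."""
    areas = np.asarray(series.area_mm2, dtype=float)
    if areas[0] <= 0:
        raise ValueError("day-1 area must be positive to define growth")
    return (areas - areas[0]) / areas[0] * 100.0


def daily_increments(series: GrowthSeries) -> np.ndarray:
    """Secondary output: day-over-day area change in percent."""
    areas = np.asarray(series.area_mm2, dtype=float)
    if (areas[:-1] <= 0).any():
        raise ValueError("areas must be positive to define increments")
    return np.diff(areas) / areas[:-1] * 100.0


def summarize_errors(records: list[AccuracyRecord], groups: list[dict],
                     by: tuple[str, ...] = ("method",)) -> list[ErrorSummary]:
    """Group accuracy records by the requested keys and summarize.

    ``groups`` carries one dict of key/value labels per record (e.g.
    ``{"method": "splint", "treatment": "CK", "illumination": "day"}``).
    """
    if not records:
        raise ValueError("no records to summarize")
    if len(groups) != len(records):
        raise ValueError("records and groups must align")
    for key in by:
        if key not in GROUP_KEYS:
            raise ValueError(f"unknown group key {key!r}; choose from {GROUP_KEYS}")
    df = pd.DataFrame([
        {**{k: g.get(k) for k in by},
         "signed": r.signed_error_pct, "abs": r.abs_error_pct}
        for r, g in zip(records, groups)
    ])
    out = []
    for keys, sub in df.groupby(list(by), sort=False, dropna=False):
        if not isinstance(keys, tuple):
            keys = (keys,)
        out.append(ErrorSummary(
            group=dict(zip(by, keys)),
            n=len(sub),
            mean_abs_error_pct=float(sub["abs"].mean()),
            mean_signed_error_pct=float(sub["signed"].mean()),
            median_signed_error_pct=float(sub["signed"].median()),
        ))
    return out


def compare_methods(summaries: list[ErrorSummary]) -> dict:
    """Rank methods by ascending mean absolute error (stable on ties).

    The report also flags the characteristic sign structure when present:
    occlusion-driven under-measurement (negative mean signed error) and
    tilt-driven over-measurement (positive).
    """
    ranked = sorted(summaries, key=lambda s: s.mean_abs_error_pct)
    notes = {}
    for s in summaries:
        m = s.group.get("method", "?")
        if s.mean_signed_error_pct < 0:
            notes[m] = "under-measures (negative signed error)"
        elif s.mean_signed_error_pct > 0:
            notes[m] = "over-measures (positive signed error)"
        else:
            notes[m] = "unbiased"
    return {
        "ranking": [s.group.get("method", "?") for s in ranked],
        "mean_abs_error_pct": {s.group.get("method", "?"): s.mean_abs_error_pct
                               for s in summaries},
        "mean_signed_error_pct": {s.group.get("method", "?"): s.mean_signed_error_pct
                                  for s in summaries},
        "sign_notes": notes,
    }
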