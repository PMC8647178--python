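"""Ranking, near-tie grouping, and recommendation of pipeline variants.

For one dataset and one evaluation measure, the predicted variants are
sorted by ascending prediction-interval width (most certain first) and
variants of similar uncertainty are grouped: the narrowest ungrouped record
anchors a group, and records join it while their width is within the
grouping tolerance (default 5%, relative to the anchor).  The recommended
variant is the one with the best point prediction — highest completeness,
or lowest R_free/R_work.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .variants import MEASURES

__all__ = [
    "rank_variants",
    "group_variants",
    "recommend",
    "RankedReport",
    "ranked_report",
]

#: Measures where a larger value is better.
_HIGHER_IS_BETTER = {"completeness"}


def _point_sort_key(measure: str, point: float) -> float:
    return -point if measure in _HIGHER_IS_BETTER else point


def _check_records(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        frame = records.copy()
    else:
        frame = pd.DataFrame(list(records))
    if frame.empty:
        raise ValueError("need at least one prediction record")
    required = {"variant_id", "measure", "point", "width"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"prediction records missing fields {sorted(missing)}")
    measures = frame["measure"].unique()
    if len(measures) != 1:
        raise ValueError(f"records mix measures {sorted(measures)}; rank one at a time")
    if measures[0] not in MEASURES:
        raise ValueError(f"unknown measure {measures[0]!r}")
    return frame


def rank_variants(records) -> pd.DataFrame:
    """Sort prediction records by ascending interval width.

    Ties are broken by the better point prediction (higher completeness,
    lower R factor), then by variant_id.  ``records`` is a DataFrame or an
    iterable of mappings with at least ``variant_id, measure, point,
    width``; all records must share one measure.
    """
    frame = _check_records(records)
    measure = frame["measure"].iloc[0]
    frame["_point_key"] = [_point_sort_key(measure, p) for p in frame["point"]]
    frame = frame.sort_values(
        ["width", "_point_key", "variant_id"], kind="mergesort"
    ).drop(columns="_point_key")
    return frame.reset_index(drop=True)


def group_variants(
    sorted_records: pd.DataFrame, tolerance: float = 0.05, relative: bool = True
) -> list[pd.DataFrame]:
    """Greedy anchored grouping of width-sorted records.

    The first record opens a group and anchors it at width w0; following
    records join while ``width <= w0 * (1 + tolerance)`` (relative mode,
    default) or ``width <= w0 + tolerance`` (absolute mode); otherwise they
    anchor a new group.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    frame = _check_records(sorted_records)
    if not frame["width"].is_monotonic_increasing:
        raise ValueError("records must be sorted by rank_variants first")
    groups: list[list[int]] = []
    anchor_width = None
    for i, width in enumerate(frame["width"]):
        limit = (
            None
            if anchor_width is None
            else (anchor_width * (1.0 + tolerance) if relative else anchor_width + tolerance)
        )
        if limit is not None and width <= limit:
            groups[-1].append(i)
        else:
            groups.append([i])
            anchor_width = width
    return [frame.iloc[g].reset_index(drop=True) for g in groups]


def recommend(records, measure: str | None = None) -> str:
    """Variant with the best point prediction for the measure.

    Best means maximum predicted completeness or minimum predicted
    R_free/R_work.  Ties go to the narrower interval width, then to the
    lexicographically smaller variant_id; the result is independent of the
    order the records are supplied in.
    """
    frame = _check_records(records)
    found = frame["measure"].iloc[0]
    if measure is not None and found != measure:
        raise ValueError(f"records are for measure {found!r}, not {measure!r}")
    measure = found
    frame["_point_key"] = [_point_sort_key(measure, p) for p in frame["point"]]
    best = frame.sort_values(["_point_key", "width", "variant_id"], kind="mergesort").iloc[0]
    return str(best["variant_id"])


@dataclass
class RankedReport:
    """Grouped uncertainty ranking plus the recommended variant."""

    measure: str
    groups: list[pd.DataFrame]
    recommended: str
    tolerance: float = 0.05

    def variant_order(self) -> list[str]:
        return [vid for g in self.groups for vid in g["variant_id"]]

    def first_group_ids(self) -> list[str]:
        return list(self.groups[0]["variant_id"]) if self.groups else []

    def to_dict(self) -> dict:
        return {
            "measure": self.measure,
            "tolerance": self.tolerance,
            "recommended": self.recommended,
            "groups": [
                g[["variant_id", "point", "interval_low", "interval_high", "width"]]
                .to_dict(orient="records")
                if {"interval_low", "interval_high"} <= set(g.columns)
                else g[["variant_id", "point", "width"]].to_dict(orient="records")
                for g in self.groups
            ],
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    def to_table(self) -> str:
        lines = [f"measure: {self.measure}   recommended: {self.recommended}"]
        for k, g in enumerate(self.groups, start=1):
            lines.append(f"group {k} (width anchor {g['width'].iloc[0]:.4g}):")
            for _, row in g.iterrows():
                lines.append(
                    f"  {row['variant_id']:<32} point={row['point']:.4f} "
                    f"width={row['width']:.4f}"
                )
        return "\n".join(lines)


def ranked_report(
    records, tolerance: float = 0.05, relative: bool = True
) -> RankedReport:
    """Rank, group, and recommend in one step for one dataset and measure."""
    ranked = rank_variants(records)
    groups = group_variants(ranked, tolerance=tolerance, relative=relative)
    return RankedReport(
        measure=str(ranked["measure"].iloc[0]),
        groups=groups,
        recommended=recommend(ranked),
        tolerance=tolerance,
    )
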