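"""CBCT-based impaction difficulty index for maxillary canines.

Five criteria are scored from the pre-treatment CBCT and summed:

* angulation between the canine long axis and the mid-sagittal plane
  (<30 deg = 1, 30-45 deg = 2, >45 deg = 3);
* vertical level of the cusp tip against the adjacent erupted incisor root
  (cemento-enamel junction = 1, middle third = 2, apical third = 3,
  above the apical third = 4);
* bucco-palatal position relative to the ideal final position (buccal = 1,
  palatal within 3 mm = 1, deep palatal beyond 3 mm = 2);
* horizontal overlap with the adjacent erupted tooth (up to half its
  width = 1, more than half = 2, complete = 3, extending beyond the next
  tooth = 4);
* rotation (properly oriented = 1, rotated = 2).

Totals run 5-15 and band into three difficulty categories: 5 = minimum,
6-10 = moderate, 11-15 = maximum. The angulation bands leave 30 and 45
degrees unassigned in prose; here the middle band is closed, [30, 45] -> 2,
so the bands partition [0, 90] without gaps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .geometry_core import as_point

__all__ = [
    "ComponentScores",
    "DifficultyScore",
    "ImpactionFeatures",
    "REFERENCE_COHORT",
    "angulation_from_geometry",
    "palatal_depth_category",
    "score_components",
    "score_table",
    "total_and_categorize",
]

VERTICAL_LEVELS = ("cej", "middle_third", "apical_third", "above_apical")
BUCCO_PALATAL = ("buccal", "palatal_within_3mm", "palatal_beyond_3mm")
HORIZONTAL_OVERLAP = ("up_to_half", "more_than_half", "complete", "beyond_adjacent")

_COMPONENT_RANGES = {
    "angulation": (1, 3),
    "vertical": (1, 4),
    "bucco_palatal": (1, 2),
    "horizontal": (1, 4),
    "rotation": (1, 2),
}
_COMPONENT_ORDER = tuple(_COMPONENT_RANGES)

CATEGORY_BANDS = {"minimum": (5, 5), "moderate": (6, 10), "maximum": (11, 15)}


@dataclass(frozen=True)
class ImpactionFeatures:
    """Raw CBCT findings for one impacted canine."""

    angulation_deg: float
    vertical_level: str
    bucco_palatal: str
    horizontal_overlap: str
    rotated: bool

    def __post_init__(self):
        if not 0.0 <= self.angulation_deg <= 90.0:
            raise ValidationError(
                f"angulation must be within [0, 90] degrees, got {self.angulation_deg}"
            )
        if self.vertical_level not in VERTICAL_LEVELS:
            raise ValidationError(f"unknown vertical level {self.vertical_level!r}")
        if self.bucco_palatal not in BUCCO_PALATAL:
            raise ValidationError(f"unknown bucco-palatal class {self.bucco_palatal!r}")
        if self.horizontal_overlap not in HORIZONTAL_OVERLAP:
            raise ValidationError(
                f"unknown horizontal overlap class {self.horizontal_overlap!r}"
            )


ComponentScores = tuple[int, int, int, int, int]


@dataclass(frozen=True)
class DifficultyScore:
    components: ComponentScores
    total: int
    category: str

    def __post_init__(self):
        for value, (name, (lo, hi)) in zip(self.components, _COMPONENT_RANGES.items()):
            if not lo <= value <= hi:
                raise ValidationError(
                    f"{name} score {value} outside its range [{lo}, {hi}]"
                )
        assert self.total == sum(self.components)
        assert 5 <= self.total <= 15


def score_components(features: ImpactionFeatures) -> ComponentScores:
    """Map raw findings to the five component scores."""
    if features.angulation_deg < 30.0:
        angulation = 1
    elif features.angulation_deg <= 45.0:
        angulation = 2
    else:
        angulation = 3
    vertical = VERTICAL_LEVELS.index(features.vertical_level) + 1
    bucco_palatal = 2 if features.bucco_palatal == "palatal_beyond_3mm" else 1
    horizontal = HORIZONTAL_OVERLAP.index(features.horizontal_overlap) + 1
    rotation = 2 if features.rotated else 1
    return (angulation, vertical, bucco_palatal, horizontal, rotation)


def total_and_categorize(components: Sequence[int]) -> DifficultyScore:
    """Sum the five component scores and band the total."""
    comps = tuple(int(c) for c in components)
    if len(comps) != 5:
        raise ValidationError(f"expected 5 component scores, got {len(comps)}")
    for value, (name, (lo, hi)) in zip(comps, _COMPONENT_RANGES.items()):
        if not lo <= value <= hi:
            raise ValidationError(f"{name} score {value} outside [{lo}, {hi}]")
    total = sum(comps)
    for category, (lo, hi) in CATEGORY_BANDS.items():
        if lo <= total <= hi:
            return DifficultyScore(comps, total, category)
    raise AssertionError("total outside [5, 15] is impossible for valid components")


def palatal_depth_category(depth_mm: float) -> str:
    """Bucco-palatal class from a signed palatal depth in mm.

    Negative depths mean buccal to the ideal position; the deep-palatal
    class starts strictly beyond 3 mm.
    """
    if depth_mm < 0:
        return "buccal"
    return "palatal_beyond_3mm" if depth_mm > 3.0 else "palatal_within_3mm"


def angulation_from_geometry(canine, plane_point, plane_normal) -> float:
    """Angle (degrees) between the canine long axis and a plane.

    The long axis is the unit vector from the root apex to the cusp tip; the
    returned value is 90 degrees minus the angle to the plane normal, so an
    axis lying in the plane scores 0 and one along the normal scores 90.
    """
    axis = as_point(canine.cusp_tip) - as_point(canine.apex)
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        raise ValidationError("cusp tip and apex coincide; long axis undefined")
    n = as_point(plane_normal)
    n_len = np.linalg.norm(n)
    if n_len < 1e-12:
        raise ValidationError("plane normal has zero length")
    sin_angle = abs(float(axis @ n)) / (norm * n_len)
    return float(np.degrees(np.arcsin(min(1.0, sin_angle))))


CaseInput = Union[ImpactionFeatures, Sequence[int]]


def score_case(case: CaseInput) -> DifficultyScore:
    """Score one canine from raw features or directly-supplied components."""
    if isinstance(case, ImpactionFeatures):
        return total_and_categorize(score_components(case))
    return total_and_categorize(case)


def score_table(
    cases: Iterable[tuple[str, CaseInput]],
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Score a cohort; returns the per-case table and category counts."""
    rows = []
    for case_id, case in cases:
        s = score_case(case)
        rows.append(
            {
                "case_id": case_id,
                **dict(zip(_COMPONENT_ORDER, s.components)),
                "total": s.total,
                "category": s.category,
            }
        )
    if not rows:
        raise ValidationError("score_table needs at least one case")
    table = pd.DataFrame(rows)
    counts = {cat: int((table["category"] == cat).sum()) for cat in CATEGORY_BANDS}
    return table, counts


#: Component scores (angulation, vertical, bucco-palatal, horizontal,
#: rotation) for a published reference cohort of 13 clinically scored
#: impacted maxillary canines, used as a worked example and regression
#: fixture for the index.
REFERENCE_COHORT: list[tuple[str, ComponentScores]] = [
    ("Case 1", (3, 3, 2, 2, 2)),
    ("Case 2 A", (2, 2, 2, 4, 2)),
    ("Case 2 B", (3, 2, 2, 2, 2)),
    ("Case 3 A", (2, 2, 2, 4, 2)),
    ("Case 3 B", (2, 2, 2, 4, 2)),
    ("Case 4", (2, 3, 2, 4, 2)),
    ("Case 5 A", (3, 2, 2, 4, 2)),
    ("Case 5 B", (3, 2, 2, 3, 2)),
    ("Case 6", (3, 2, 2, 3, 2)),
    ("Case 7", (3, 2, 1, 3, 2)),
    ("Case 8", (3, 2, 1, 3, 2)),
    ("Case 9", (3, 3, 1, 2, 1)),
    ("Case 10", (3, 4, 1, 1, 2)),
]
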