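"""Composite motor-impairment scores and percentile-based severity groups.

Muscle weakness is graded with Manual Muscle Testing (MMT, ordinal 0-5 per
muscle group) for elbow extensors, elbow supinators and wrist extensors;
the composite weakness score is their sum (0-15, higher = stronger).
Spasticity is graded with the Modified Ashworth Scale (MAS, ordinal
0/1/1+/2/3/4) for elbow flexors, elbow pronators and wrist flexors; the
composite spasticity score is the sum after coding the 1+ grade as 1.5
(0-12, higher = more spastic).

Severity groups follow the cohort's quartiles: scores strictly beyond the
75th percentile on the less-impaired side are "low", strictly beyond the
25th percentile on the impaired side are "severe", and everything on or
between the cut points is "moderate".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

MMT_ITEMS = ("elbow_extensors", "elbow_supinators", "wrist_extensors")
MAS_ITEMS = ("elbow_flexors", "elbow_pronators", "wrist_flexors")

#: numeric coding of the MAS ordinal set; "1+" sits between 1 and 2
MAS_NUMERIC: dict[str, float] = {"0": 0.0, "1": 1.0, "1+": 1.5, "2": 2.0, "3": 3.0, "4": 4.0}

WEAKNESS_MAX = 15.0
SPASTICITY_MAX = 12.0


def _mas_value(grade, mapping: dict[str, float] | None = None) -> float:
    mapping = MAS_NUMERIC if mapping is None else mapping
    key = str(grade).strip()
    if key.endswith(".0"):
        key = key[:-2]
    if key not in mapping:
        raise ValueError(f"unknown MAS grade {grade!r}; expected one of {sorted(mapping)}")
    return mapping[key]


def composite_weakness(mmt_items: Sequence[float]) -> float:
    """Sum of the three MMT items (0-15; higher = stronger)."""
    items = [float(v) for v in mmt_items]
    if len(items) != 3:
        raise ValueError("composite weakness needs exactly three MMT items")
    for v in items:
        if not 0.0 <= v <= 5.0:
            raise ValueError(f"MMT item {v} outside the 0-5 range")
    return float(sum(items))


def composite_spasticity(mas_items: Sequence, mapping: dict[str, float] | None = None) -> float:
    """Sum of the three MAS items after numeric coding (0-12; higher = more spastic)."""
    if len(mas_items) != 3:
        raise ValueError("composite spasticity needs exactly three MAS items")
    return float(sum(_mas_value(g, mapping) for g in mas_items))


@dataclass
class ClinicalProfile:
    """Per-subject clinical evaluation."""

    subject_id: str
    mmt_items: tuple[float, float, float]
    mas_items: tuple[str, str, str]
    classification_level: str | None = None

    def __post_init__(self) -> None:
        self.mmt_items = tuple(float(v) for v in self.mmt_items)  # type: ignore[assignment]
        self.mas_items = tuple(str(v) for v in self.mas_items)  # type: ignore[assignment]
        # validate eagerly
        composite_weakness(self.mmt_items)
        composite_spasticity(self.mas_items)

    @property
    def weakness(self) -> float:
        return composite_weakness(self.mmt_items)

    @property
    def spasticity(self) -> float:
        return composite_spasticity(self.mas_items)

    def score(self, covariate: str) -> float:
        if covariate == "weakness":
            return self.weakness
        if covariate == "spasticity":
            return self.spasticity
        raise KeyError(f"unknown covariate {covariate!r}")


@dataclass(frozen=True)
class ImpairmentGroup:
    label: str  # "low" | "moderate" | "severe"
    cut_points: tuple[float, float]  # (p25, p75) on the composite scale


def assign_group(
    score: float,
    cohort_scores: Iterable[float],
    direction: str = "higher_is_less_impaired",
) -> ImpairmentGroup:
    """Assign a subject to low/moderate/severe impairment by cohort quartiles.

    ``direction`` is ``"higher_is_less_impaired"`` for the weakness composite
    (a strong child scores high) and ``"lower_is_less_impaired"`` for the
    spasticity composite.  Scores equal to a cut point fall into "moderate".
    """
    scores = np.asarray(list(cohort_scores), dtype=float)
    if scores.size == 0:
        raise ValueError("cohort_scores must be nonempty")
    p25, p75 = np.percentile(scores, [25.0, 75.0])
    if direction == "higher_is_less_impaired":
        label = "low" if score > p75 else ("severe" if score < p25 else "moderate")
    elif direction == "lower_is_less_impaired":
        label = "low" if score < p25 else ("severe" if score > p75 else "moderate")
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return ImpairmentGroup(label, (float(p25), float(p75)))


def describe(scores: Iterable[float]) -> tuple[float, float]:
    """Median and interquartile range (p75 - p25, linear interpolation)."""
    arr = np.asarray(list(scores), dtype=float)
    if arr.size == 0:
        raise ValueError("scores must be nonempty")
    p25, p50, p75 = np.percentile(arr, [25.0, 50.0, 75.0])
    return float(p50), float(p75 - p25)
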