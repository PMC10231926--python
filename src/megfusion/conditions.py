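"""Canonical condition ordering shared by every analysis stage.

The experiment shows 5 unique exemplar images from each of 4 object
categories (face, animal, house, man-made), and each image ends up either
recognized (R) or unrecognized (U).  All 40 x 40 representational
dissimilarity matrices (RDMs) in this package use one fixed ordering:

* recognized block first (rows/cols 0-19), unrecognized block second
  (rows/cols 20-39), so that R-R dissimilarities occupy the upper-left
  quadrant and U-U the bottom-right;
* within a block, exemplars are grouped by category in the order
  face, animal, house, man_made, exemplars 1-5 within each category.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

CATEGORIES: tuple[str, ...] = ("face", "animal", "house", "man_made")
OUTCOMES: tuple[str, ...] = ("recognized", "unrecognized")
N_EXEMPLARS_PER_CATEGORY = 5
N_CATEGORIES = len(CATEGORIES)
N_REAL_EXEMPLARS = N_CATEGORIES * N_EXEMPLARS_PER_CATEGORY  # 20
N_CONDITIONS = 2 * N_REAL_EXEMPLARS  # 40


@dataclass(frozen=True)
class Condition:
    """One cell of the 40-condition design."""

    outcome: str
    category: str
    exemplar: int  # 1-based within category

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if not 1 <= self.exemplar <= N_EXEMPLARS_PER_CATEGORY:
            raise ValueError(f"exemplar must be 1-5, got {self.exemplar}")


def condition_index() -> list[Condition]:
    """The fixed 40-condition ordering (recognized block first)."""
    return [
        Condition(outcome, category, ex)
        for outcome in OUTCOMES
        for category in CATEGORIES
        for ex in range(1, N_EXEMPLARS_PER_CATEGORY + 1)
    ]


def condition_position(outcome: str, category: str, exemplar: int) -> int:
    """Row/column of a condition in the canonical 40 x 40 layout."""
    cond = Condition(outcome, category, exemplar)
    block = OUTCOMES.index(cond.outcome) * N_REAL_EXEMPLARS
    return (
        block
        + CATEGORIES.index(cond.category) * N_EXEMPLARS_PER_CATEGORY
        + (cond.exemplar - 1)
    )


def exemplar_position(category: str, exemplar: int) -> int:
    """Position of a real image in the 20-exemplar (single-outcome) layout."""
    return condition_position("recognized", category, exemplar)


def quadrant_slices(outcome: str) -> tuple[slice, slice]:
    """Row/column slices of the within-outcome quadrant for ``outcome``."""
    if outcome not in OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}")
    start = OUTCOMES.index(outcome) * N_REAL_EXEMPLARS
    sl = slice(start, start + N_REAL_EXEMPLARS)
    return sl, sl


def category_of_position(pos: int) -> str:
    """Category of the condition at canonical position ``pos``."""
    if not 0 <= pos < N_CONDITIONS:
        raise ValueError(f"position out of range: {pos}")
    return CATEGORIES[(pos % N_REAL_EXEMPLARS) // N_EXEMPLARS_PER_CATEGORY]


def outcome_of_position(pos: int) -> str:
    if not 0 <= pos < N_CONDITIONS:
        raise ValueError(f"position out of range: {pos}")
    return OUTCOMES[pos // N_REAL_EXEMPLARS]


def category_labels_20() -> np.ndarray:
    """Integer category codes (0-3) for the 20-exemplar layout."""
    return np.repeat(np.arange(N_CATEGORIES), N_EXEMPLARS_PER_CATEGORY)
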