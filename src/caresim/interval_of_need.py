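"""Interval-of-need dependency classification.

The *interval of need* (Isaacs & Neville) grades dependency by the frequency
with which care is required:

* ``HIGH`` — needs 24-hour care,
* ``MEDIUM`` — needs help at regular times daily,
* ``LOW`` — needs help less than daily,
* ``INDEPENDENT`` — free from care.

Two item "dialects" are supported, mirroring the two instruments the scale is
operationalised with in ageing cohort studies:

* ``"full"`` — the richer set including proxy-interview items and a severe
  cognitive impairment rule (MMSE 0-9 forces high dependency);
* ``"brief"`` — a shorter self-report set without proxy items or an MMSE rule.

Classification evaluates the high, medium and low rules in that order; the
first level whose rule fires wins.  ``INDEPENDENT`` is returned only when no
rule fires *and* no dialect item is missing — an individual with unanswered
items and no positive trigger is unclassifiable rather than independent.

Cognition is graded separately from the Mini-Mental State Examination (MMSE,
0-30, lower = more impaired): severe 0-9, moderate 10-20, mild 21-26, normal
27-30.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

from .exceptions import InputDomainError, UnclassifiableError

__all__ = [
    "IntervalOfNeed",
    "CognitionCategory",
    "CareNeedItems",
    "DIALECT_ITEMS",
    "categorise_mmse",
    "classify_interval_of_need",
    "combine_physical_and_cognition",
]


class IntervalOfNeed(enum.IntEnum):
    """Ordered dependency level; larger means more dependent."""

    INDEPENDENT = 0
    LOW = 1
    MEDIUM = 2
    HIGH = 3

    def __str__(self) -> str:  # tidy CSV / log output
        return self.name.lower()


class CognitionCategory(enum.IntEnum):
    """Cognitive status band from the MMSE score; larger = more impaired."""

    NORMAL = 0
    MILD = 1
    MODERATE = 2
    SEVERE = 3

    def __str__(self) -> str:
        return self.name.lower()


#: Inclusive MMSE score ranges; the four bands partition 0-30 exactly.
MMSE_RANGES: dict[CognitionCategory, tuple[int, int]] = {
    CognitionCategory.SEVERE: (0, 9),
    CognitionCategory.MODERATE: (10, 20),
    CognitionCategory.MILD: (21, 26),
    CognitionCategory.NORMAL: (27, 30),
}


def categorise_mmse(score: int) -> CognitionCategory:
    """Map an MMSE score (integer 0-30) to its cognition band.

    Raises
    ------
    InputDomainError
        If ``score`` is not an integer in [0, 30].
    """
    # accept python and numpy integers; reject bools, floats and strings
    if isinstance(score, bool) or not hasattr(score, "__index__"):
        raise InputDomainError(f"MMSE score must be an integer, got {score!r}")
    score = int(score)
    if not 0 <= score <= 30:
        raise InputDomainError(f"MMSE score must lie in [0, 30], got {score}")
    for category, (lo, hi) in MMSE_RANGES.items():
        if lo <= score <= hi:
            return category
    raise AssertionError("unreachable: MMSE bands partition 0-30")


@dataclass
class CareNeedItems:
    """Care-need indicators for one individual.

    ``None`` means the item was not observed.  ``dialect`` decides which
    indicators are interpretable; see :data:`DIALECT_ITEMS`.
    """

    dialect: str
    help_toilet: Optional[bool] = None
    chairfast_or_bedfast: Optional[bool] = None
    incontinent: Optional[bool] = None
    help_shoes_socks: Optional[bool] = None
    help_feed_proxy: Optional[bool] = None
    help_dress_proxy: Optional[bool] = None
    help_hot_meal: Optional[bool] = None
    help_bathe: Optional[bool] = None
    help_cut_toenails: Optional[bool] = None
    help_heavy_housework: Optional[bool] = None
    help_shopping_or_light_housework: Optional[bool] = None
    difficulty_push_pull: Optional[bool] = None
    difficulty_house_garden_work: Optional[bool] = None
    household_tasks_proxy: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.dialect not in DIALECT_ITEMS:
            raise InputDomainError(
                f"unknown dialect {self.dialect!r}; expected one of {sorted(DIALECT_ITEMS)}"
            )

    def item(self, name: str) -> Optional[bool]:
        return getattr(self, name)


#: Items interpretable in each dialect, grouped by the level they can trigger.
DIALECT_ITEMS: dict[str, dict[str, tuple[str, ...]]] = {
    "full": {
        "high": (
            "help_toilet",
            "chairfast_or_bedfast",
            "incontinent",
            "help_shoes_socks",
            "help_feed_proxy",
            "help_dress_proxy",
        ),
        "medium": ("help_shoes_socks", "help_hot_meal", "help_dress_proxy"),
        "low": (
            "help_bathe",
            "help_cut_toenails",
            "help_heavy_housework",
            "help_shopping_or_light_housework",
            "household_tasks_proxy",
        ),
    },
    "brief": {
        "high": ("help_toilet", "chairfast_or_bedfast", "incontinent", "help_shoes_socks"),
        "medium": ("help_shoes_socks", "help_hot_meal"),
        "low": ("help_bathe", "difficulty_push_pull", "difficulty_house_garden_work"),
    },
}


def _all_dialect_items(dialect: str) -> tuple[str, ...]:
    seen: list[str] = []
    for group in DIALECT_ITEMS[dialect].values():
        for name in group:
            if name not in seen:
                seen.append(name)
    return tuple(seen)


def _true(value: Optional[bool]) -> bool:
    return value is True


def _high_rule(items: CareNeedItems, mmse: Optional[int]) -> bool:
    if items.dialect == "full":
        if mmse is not None and categorise_mmse(mmse) is CognitionCategory.SEVERE:
            return True
        return (
            _true(items.help_toilet)
            or _true(items.chairfast_or_bedfast)
            or (_true(items.incontinent) and _true(items.help_shoes_socks))
            or _true(items.help_feed_proxy)
            or (_true(items.incontinent) and _true(items.help_dress_proxy))
        )
    return (
        _true(items.help_toilet)
        or _true(items.chairfast_or_bedfast)
        or (_true(items.incontinent) and _true(items.help_shoes_socks))
    )


def _medium_rule(items: CareNeedItems) -> bool:
    if items.dialect == "full":
        return (
            _true(items.help_shoes_socks)
            or _true(items.help_hot_meal)
            or _true(items.help_dress_proxy)
        )
    return _true(items.help_shoes_socks) or _true(items.help_hot_meal)


def _low_rule(items: CareNeedItems) -> bool:
    if items.dialect == "full":
        return (
            _true(items.help_bathe)
            or _true(items.help_cut_toenails)
            or _true(items.help_heavy_housework)
            or _true(items.help_shopping_or_light_housework)
            or _true(items.household_tasks_proxy)
        )
    return (
        _true(items.help_bathe)
        or _true(items.difficulty_push_pull)
        or _true(items.difficulty_house_garden_work)
    )


def classify_interval_of_need(
    items: CareNeedItems, mmse: Optional[int] = None
) -> IntervalOfNeed:
    """Classify dependency from care-need items (and, in the full dialect, MMSE).

    Rules are checked high → medium → low; the first match wins.  A missing
    item never triggers a rule, and a conjunction (incontinence + dressing
    help) requires both parts present-and-true.  ``INDEPENDENT`` requires that
    no rule fired *and* every dialect item (plus MMSE in the full dialect) is
    observed; otherwise the individual is unclassifiable.

    Raises
    ------
    UnclassifiableError
        If no rule fires but one or more items are missing.
    """
    relevant = _all_dialect_items(items.dialect)
    if all(items.item(name) is None for name in relevant) and (
        items.dialect == "brief" or mmse is None
    ):
        raise UnclassifiableError("all care-need items missing")

    if _high_rule(items, mmse):
        return IntervalOfNeed.HIGH
    if _medium_rule(items):
        return IntervalOfNeed.MEDIUM
    if _low_rule(items):
        return IntervalOfNeed.LOW

    missing = [name for name in relevant if items.item(name) is None]
    if items.dialect == "full" and mmse is None:
        missing.append("mmse")
    if missing:
        raise UnclassifiableError(
            "not classifiable as dependent and cannot be confirmed independent; "
            f"missing items: {', '.join(missing)}"
        )
    return IntervalOfNeed.INDEPENDENT


def combine_physical_and_cognition(
    physical: IntervalOfNeed, cognition: CognitionCategory
) -> IntervalOfNeed:
    """Merge physical dependency with cognitive status into an interval of need.

    Severe cognitive impairment (MMSE 0-9) alone implies 24-hour care, so it
    floors the combined level at ``HIGH``; milder impairment imposes no floor
    (its influence on dependency flows through the transition models instead).
    """
    floor = (
        IntervalOfNeed.HIGH
        if cognition is CognitionCategory.SEVERE
        else IntervalOfNeed.INDEPENDENT
    )
    return max(physical, floor)
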