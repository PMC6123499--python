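"""Independent literal transcription of the interval-of-need rules.

Deliberately written as plain nested conditionals, row by row, without
reference to the package's rule tables, so the classifier can be checked
against it by exhaustive enumeration.
"""

from caresim import IntervalOfNeed


def reference_classify_full(items: dict, mmse: int) -> IntervalOfNeed:
    """Richer dialect: proxy items and the severe-cognition rule."""
    if 0 <= mmse <= 9:
        return IntervalOfNeed.HIGH
    if items["help_toilet"]:
        return IntervalOfNeed.HIGH
    if items["chairfast_or_bedfast"]:
        return IntervalOfNeed.HIGH
    if items["incontinent"] and items["help_shoes_socks"]:
        return IntervalOfNeed.HIGH
    if items["help_feed_proxy"]:
        return IntervalOfNeed.HIGH
    if items["incontinent"] and items["help_dress_proxy"]:
        return IntervalOfNeed.HIGH
    if items["help_shoes_socks"] or items["help_hot_meal"] or items["help_dress_proxy"]:
        return IntervalOfNeed.MEDIUM
    if (
        items["help_bathe"]
        or items["help_cut_toenails"]
        or items["help_heavy_housework"]
        or items["help_shopping_or_light_housework"]
        or items["household_tasks_proxy"]
    ):
        return IntervalOfNeed.LOW
    return IntervalOfNeed.INDEPENDENT


def reference_classify_brief(items: dict) -> IntervalOfNeed:
    """Shorter self-report dialect."""
    if items["help_toilet"] or items["chairfast_or_bedfast"]:
        return IntervalOfNeed.HIGH
    if items["incontinent"] and items["help_shoes_socks"]:
        return IntervalOfNeed.HIGH
    if items["help_shoes_socks"] or items["help_hot_meal"]:
        return IntervalOfNeed.MEDIUM
    if (
        items["help_bathe"]
        or items["difficulty_push_pull"]
        or items["difficulty_house_garden_work"]
    ):
        return IntervalOfNeed.LOW
    return IntervalOfNeed.INDEPENDENT


FULL_ITEMS = (
    "help_toilet",
    "chairfast_or_bedfast",
    "incontinent",
    "help_shoes_socks",
    "help_feed_proxy",
    "help_dress_proxy",
    "help_hot_meal",
    "help_bathe",
    "help_cut_toenails",
    "help_heavy_housework",
    "help_shopping_or_light_housework",
    "household_tasks_proxy",
)

BRIEF_ITEMS = (
    "help_toilet",
    "chairfast_or_bedfast",
    "incontinent",
    "help_shoes_socks",
    "help_hot_meal",
    "help_bathe",
    "difficulty_push_pull",
    "difficulty_house_garden_work",
)
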