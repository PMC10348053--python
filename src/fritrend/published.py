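"""Published Iowa Fluoride Study summary count tables.

The IFS report on generalized-fluorosis trends prints age × severity
category count tables for three tooth groups at three analysis levels:
person-level mean-FRI categories, tooth-level mean-FRI categories, and
the five-category generalized-fluorosis outcome. The underlying cohort
data are not deposited, but the printed counts fully determine the
ordinal gamma trend statistics, so these matrices are the exact
reference surface for validating :func:`fritrend.assoc_stats.gk_gamma`
and the reporting layer.

Rows are exam ages in years (late-erupting teeth start at 13 because
they are unerupted at the age-9 exam); columns are severity categories
in increasing order.
"""

from __future__ import annotations

from .assoc_stats import ContingencyTable
from .severity import GeneralizedCategory, MeanFriCategory

__all__ = [
    "PERSON_LEVEL_TABLES",
    "TOOTH_LEVEL_TABLES",
    "GENERALIZED_TABLES",
    "published_table",
]

_MEAN_FRI_COLS = tuple(c.label for c in MeanFriCategory)
_GENERALIZED_COLS = tuple(c.label for c in GeneralizedCategory)

#: Person-level mean-FRI category counts by exam age (n = 282/291/279).
PERSON_LEVEL_TABLES: dict[str, ContingencyTable] = {
    "early_erupting": ContingencyTable.from_counts(
        [[84, 146, 35, 17], [127, 127, 23, 5], [164, 103, 12, 3], [173, 100, 5, 4]],
        row_levels=(9, 13, 17, 23),
        col_levels=_MEAN_FRI_COLS,
    ),
    "late_erupting": ContingencyTable.from_counts(
        [[114, 130, 35, 12], [167, 106, 10, 8], [192, 86, 8, 5]],
        row_levels=(13, 17, 23),
        col_levels=_MEAN_FRI_COLS,
    ),
    "maxillary_incisors": ContingencyTable.from_counts(
        [[100, 87, 59, 33], [141, 85, 37, 16], [181, 59, 33, 6], [192, 59, 23, 5]],
        row_levels=(9, 13, 17, 23),
        col_levels=_MEAN_FRI_COLS,
    ),
}

#: Tooth-level mean-FRI category counts (n = 3269/4251/1068 teeth).
TOOTH_LEVEL_TABLES: dict[str, ContingencyTable] = {
    "early_erupting": ContingencyTable.from_counts(
        [
            [2249, 428, 323, 269],
            [2577, 338, 220, 134],
            [2791, 252, 152, 74],
            [2847, 239, 133, 50],
        ],
        row_levels=(9, 13, 17, 23),
        col_levels=_MEAN_FRI_COLS,
    ),
    "late_erupting": ContingencyTable.from_counts(
        [[2871, 798, 402, 180], [3368, 608, 160, 115], [3543, 501, 131, 76]],
        row_levels=(13, 17, 23),
        col_levels=_MEAN_FRI_COLS,
    ),
    "maxillary_incisors": ContingencyTable.from_counts(
        [[547, 216, 179, 126], [683, 201, 121, 63], [792, 151, 98, 27], [831, 143, 75, 19]],
        row_levels=(9, 13, 17, 23),
        col_levels=_MEAN_FRI_COLS,
    ),
}

#: Five-category generalized-fluorosis counts, least to most severe.
GENERALIZED_TABLES: dict[str, ContingencyTable] = {
    "early_erupting": ContingencyTable.from_counts(
        [
            [84, 35, 46, 40, 77],
            [127, 73, 29, 41, 12],
            [164, 66, 18, 27, 7],
            [173, 63, 21, 21, 4],
        ],
        row_levels=(9, 13, 17, 23),
        col_levels=_GENERALIZED_COLS,
    ),
    "late_erupting": ContingencyTable.from_counts(
        [[114, 71, 7, 74, 25], [167, 59, 8, 48, 9], [192, 51, 1, 41, 6]],
        row_levels=(13, 17, 23),
        col_levels=_GENERALIZED_COLS,
    ),
    "maxillary_incisors": ContingencyTable.from_counts(
        [
            [100, 28, 0, 64, 87],
            [141, 23, 1, 74, 40],
            [181, 16, 0, 55, 27],
            [192, 11, 0, 53, 23],
        ],
        row_levels=(9, 13, 17, 23),
        col_levels=_GENERALIZED_COLS,
    ),
}

_LEVELS = {
    "person": PERSON_LEVEL_TABLES,
    "tooth": TOOTH_LEVEL_TABLES,
    "generalized": GENERALIZED_TABLES,
}


def published_table(level: str, group: str) -> ContingencyTable:
    """Look up one published count table by analysis level and tooth group."""
    try:
        return _LEVELS[level][group]
    except KeyError:
        raise KeyError(
            f"no published table for level={level!r}, group={group!r}; "
            f"levels: {sorted(_LEVELS)}, groups: {sorted(PERSON_LEVEL_TABLES)}"
        ) from None
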