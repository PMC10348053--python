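"""Severity measures built on aligned zone scores.

Longitudinal comparisons are only meaningful on zones observed at every
age being compared, so all summaries start from an *aligned* zone set:
``all_ages`` alignment keeps zones scored at every applicable wave (4
waves for early-erupting teeth and maxillary incisors, 3 for
late-erupting teeth), ``pairwise`` alignment keeps zones scored at both
ages of one adjacent pair. Zones missing anywhere are dropped, never
imputed.

Three severity measures are computed on the aligned set:

* person-level mean FRI — the mean score over all of a participant's
  retained zones in a tooth group;
* tooth-level mean FRI — the mean over a tooth's retained zones (1–4);
* a five-category generalized-fluorosis classification driven by
  per-tooth maximum scores (see :func:`classify_generalized`).

Mean scores are binned into the four ranges 0, 0.01–0.50, 0.51–1.00 and
1.01–3.00 for tabulation and ordinal trend testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Literal

import numpy as np
import pandas as pd

from .fri_data import CohortDataset, ToothGroupName, group_waves, tooth_group_members

__all__ = [
    "MeanFriCategory",
    "GeneralizedCategory",
    "AlignedZoneSet",
    "align_zones",
    "person_mean_fri",
    "tooth_mean_fri",
    "categorize_mean_fri",
    "classify_generalized",
    "summarize_severity",
]

_ZERO_TOL = 1e-12


class MeanFriCategory(IntEnum):
    """Ordered mean-FRI score bins: 0 < 0.01–0.50 < 0.51–1.00 < 1.01–3.00."""

    C0 = 0
    C1 = 1
    C2 = 2
    C3 = 3

    @property
    def label(self) -> str:
        return ("0", "0.01-0.50", "0.51-1.00", "1.01-3.00")[self.value]


class GeneralizedCategory(IntEnum):
    """Five-level generalized-fluorosis classification, least to most severe."""

    no_fluorosis = 0
    any_questionable = 1
    any_positive = 2
    generalized_questionable = 3
    generalized_positive = 4

    @property
    def label(self) -> str:
        return (
            "No Fluorosis",
            "Any Questionable",
            "Any Positive",
            "Generalized Questionable",
            "Generalized Positive",
        )[self.value]


@dataclass
class AlignedZoneSet:
    """Zones of one tooth group retained at every age under comparison.

    ``scores`` is a frame indexed by (participant_id, tooth, zone) with
    one column per age; every retained zone has a primary score at every
    listed age.
    """

    mode: Literal["all_ages", "pairwise"]
    group: ToothGroupName
    ages: tuple[int, ...]
    scores: pd.DataFrame

    def __post_init__(self) -> None:
        self.ages = tuple(self.ages)

    @property
    def participants(self) -> list[str]:
        if self.scores.empty:
            return []
        return sorted(self.scores.index.get_level_values("participant_id").unique())

    @property
    def n_participants(self) -> int:
        return len(self.participants)

    def __len__(self) -> int:
        return len(self.scores)


def align_zones(
    data: CohortDataset,
    group: ToothGroupName | str,
    ages: tuple[int, ...] | None = None,
    mode: Literal["all_ages", "pairwise"] = "all_ages",
) -> AlignedZoneSet:
    """Retain (participant, tooth, zone) keys scored at every listed age.

    Only primary exam records count. ``ages`` defaults to the group's
    applicable waves for ``all_ages`` mode and must be a length-2
    subsequence of the dataset waves for ``pairwise`` mode. An empty
    result is returned as an empty aligned set, not an error.
    """
    group = ToothGroupName(group)
    if ages is None:
        if mode == "pairwise":
            raise ValueError("pairwise mode requires an explicit age pair")
        ages = group_waves(group, data.waves)
    ages = tuple(ages)
    if mode == "pairwise" and len(ages) != 2:
        raise ValueError(f"pairwise mode takes exactly 2 ages, got {ages}")
    if any(a not in data.waves for a in ages):
        raise ValueError(f"ages {ages} not all among dataset waves {data.waves}")

    members = tooth_group_members(group)
    df = data.primary
    df = df[df["tooth"].isin(members) & df["exam_age"].isin(ages)]
    wide = df.pivot_table(
        index=["participant_id", "tooth", "zone"],
        columns="exam_age",
        values="fri",
        aggfunc="first",
    )
    wide = wide.reindex(columns=list(ages)).dropna(how="any")
    return AlignedZoneSet(mode=mode, group=group, ages=ages, scores=wide.astype(int))


def person_mean_fri(aligned: AlignedZoneSet, participant: str, age: int) -> float:
    """Mean FRI over all of a participant's retained zones at one age."""
    _check_age(aligned, age)
    try:
        sub = aligned.scores.xs(participant, level="participant_id")
    except KeyError:
        raise KeyError(f"participant {participant!r} has no retained zones") from None
    return float(sub[age].mean())


def tooth_mean_fri(aligned: AlignedZoneSet, participant: str, tooth: int, age: int) -> float:
    """Mean FRI over one tooth's retained zones (1–4 of them) at one age."""
    _check_age(aligned, age)
    try:
        sub = aligned.scores.xs((participant, tooth), level=["participant_id", "tooth"])
    except KeyError:
        raise KeyError(f"no retained zones for participant {participant!r} tooth {tooth}") from None
    return float(sub[age].mean())


def _check_age(aligned: AlignedZoneSet, age: int) -> None:
    if age not in aligned.ages:
        raise KeyError(f"age {age} not in aligned ages {aligned.ages}")


def person_means(aligned: AlignedZoneSet) -> pd.DataFrame:
    """Per-participant mean FRI, one row per participant, one column per age."""
    return aligned.scores.groupby(level="participant_id").mean()


def tooth_means(aligned: AlignedZoneSet) -> pd.DataFrame:
    """Per-tooth mean FRI, one row per (participant, tooth), column per age."""
    return aligned.scores.groupby(level=["participant_id", "tooth"]).mean()


def categorize_mean_fri(score: float) -> MeanFriCategory:
    """Bin a mean FRI score into the four ordered reporting ranges.

    The bins are 0, (0, 0.5], (0.5, 1.0] and (1.0, 3.0]; a score is
    "zero" within 1e-12. Scores outside [0, 3] are rejected.
    """
    if not 0 - _ZERO_TOL <= score <= 3 + _ZERO_TOL:
        raise ValueError(f"mean FRI score outside [0, 3]: {score}")
    if score <= _ZERO_TOL:
        return MeanFriCategory.C0
    if score <= 0.5:
        return MeanFriCategory.C1
    if score <= 1.0:
        return MeanFriCategory.C2
    return MeanFriCategory.C3


def categorize_mean_fri_array(scores) -> np.ndarray:
    """Vectorized :func:`categorize_mean_fri` returning integer codes 0-3."""
    s = np.asarray(scores, dtype=float)
    if np.any((s < -_ZERO_TOL) | (s > 3 + _ZERO_TOL)):
        raise ValueError("mean FRI scores outside [0, 3]")
    return (
        (s > _ZERO_TOL).astype(int) + (s > 0.5).astype(int) + (s > 1.0).astype(int)
    )


def classify_generalized(tooth_max_scores) -> GeneralizedCategory:
    """Classify a participant's generalized-fluorosis presentation.

    ``tooth_max_scores`` holds the maximum FRI score over the available
    zones of each available tooth in the tooth group. In decreasing
    severity, with inclusive 50% thresholds on available teeth:

    * generalized_positive — ≥50% of teeth have a maximum of at least 2;
    * generalized_questionable — ≥50% of teeth have a maximum of at
      least 1 (but not generalized positive);
    * any_positive — some tooth reaches 2, short of either threshold;
    * any_questionable — some tooth reaches 1, none reaches the above;
    * no_fluorosis — every zone of every tooth scored 0.
    """
    maxima = np.asarray(list(tooth_max_scores), dtype=int)
    if maxima.size == 0:
        raise ValueError("no available teeth to classify")
    if np.any((maxima < 0) | (maxima > 3)):
        raise ValueError("tooth maxima must be FRI scores 0-3")
    n = maxima.size
    if np.sum(maxima >= 2) * 2 >= n:
        return GeneralizedCategory.generalized_positive
    if np.sum(maxima >= 1) * 2 >= n:
        return GeneralizedCategory.generalized_questionable
    if np.any(maxima >= 2):
        return GeneralizedCategory.any_positive
    if np.any(maxima >= 1):
        return GeneralizedCategory.any_questionable
    return GeneralizedCategory.no_fluorosis


def generalized_categories(aligned: AlignedZoneSet) -> pd.DataFrame:
    """Per-participant generalized category at each aligned age.

    Per-tooth maxima are taken over the retained zones of the aligned
    set, so the available-teeth denominator is constant across waves.
    """
    tooth_max = aligned.scores.groupby(level=["participant_id", "tooth"]).max()
    out = {}
    for age in aligned.ages:
        out[age] = tooth_max[age].groupby(level="participant_id").apply(
            lambda m: int(classify_generalized(m.to_numpy()))
        )
    return pd.DataFrame(out)


def summarize_severity(
    data: CohortDataset,
    group: ToothGroupName | str,
    level: Literal["person", "tooth", "generalized"],
    ages: tuple[int, ...] | None = None,
) -> pd.DataFrame:
    """Count (and percent) of units per severity category per exam age.

    Uses all-ages alignment so the denominator — aligned participants
    (person/generalized levels) or aligned teeth (tooth level) — is the
    same at every wave. Returns a tidy frame with columns
    ``group, level, category, category_label, age, count, percent``;
    categories with zero counts are included.
    """
    group = ToothGroupName(group)
    aligned = align_zones(data, group, ages=ages, mode="all_ages")
    if level == "person":
        codes = person_means(aligned).apply(categorize_mean_fri_array)
        cats: type[MeanFriCategory] | type[GeneralizedCategory] = MeanFriCategory
    elif level == "tooth":
        codes = tooth_means(aligned).apply(categorize_mean_fri_array)
        cats = MeanFriCategory
    elif level == "generalized":
        codes = generalized_categories(aligned)
        cats = GeneralizedCategory
    else:
        raise ValueError(f"unknown level {level!r}")

    n = len(codes)
    rows = []
    for age in aligned.ages:
        counts = codes[age].value_counts().reindex([c.value for c in cats], fill_value=0)
        for cat in cats:
            count = int(counts[cat.value])
            rows.append(
                {
                    "group": group.value,
                    "level": level,
                    "category": int(cat),
                    "category_label": cat.label,
                    "age": age,
                    "count": count,
                    "percent": 100.0 * count / n if n else float("nan"),
                }
            )
    return pd.DataFrame(rows)


def severity_contingency(summary: pd.DataFrame) -> pd.DataFrame:
    """Pivot a :func:`summarize_severity` frame to an age × category count table."""
    return summary.pivot_table(
        index="age", columns="category", values="count", aggfunc="sum"
    ).sort_index()
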