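"""Domain model for zone-level Fluorosis Risk Index (FRI) exam data.

The FRI scores up to four zones per permanent tooth — three horizontal
buccal thirds plus the incisal edge / occlusal table — on an ordinal
0–3 scale:

    0  no fluorosis (also used for non-fluoride opacities, flagged)
    1  questionable fluorosis, under half of the zone affected
    2  positive fluorosis, at least half of the zone affected
    3  severe fluorosis: pitting, staining, or deformity

A cohort is a long table of such zone scores collected at repeated
exam waves (ages 9, 13, 17 and 23 years in the Iowa Fluoride Study
design this package targets), together with optional participant-level
bleaching/whitening product usage per inter-exam interval.

Teeth are identified by FDI two-digit notation (quadrant 1–4, position
1–8). Analyses run on three tooth groups: early-erupting teeth
(permanent incisors and first molars), the maxillary incisors (a
subset of the early-erupting group), and late-erupting teeth (canines,
premolars and second molars). Third molars are excluded.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "Zone",
    "ZoneScore",
    "ToothGroupName",
    "tooth_group_members",
    "group_waves",
    "CohortDataset",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "universal_to_fdi",
    "DEFAULT_WAVES",
]

DEFAULT_WAVES: tuple[int, ...] = (9, 13, 17, 23)

FRI_LEVELS = (0, 1, 2, 3)


class Zone(str, Enum):
    """The four scoreable zones of a tooth surface."""

    incisal_third = "incisal_third"
    middle_third = "middle_third"
    cervical_third = "cervical_third"
    occlusal_incisal = "occlusal_incisal"


#: Accepted aliases for zone labels on input; extend via ``zone_aliases``
#: in :func:`read_cohort` for site-specific files.
ZONE_ALIASES: dict[str, Zone] = {
    "incisal_third": Zone.incisal_third,
    "incisal": Zone.incisal_third,
    "middle_third": Zone.middle_third,
    "middle": Zone.middle_third,
    "cervical_third": Zone.cervical_third,
    "cervical": Zone.cervical_third,
    "occlusal_incisal": Zone.occlusal_incisal,
    "occlusal": Zone.occlusal_incisal,
    "incisal_edge": Zone.occlusal_incisal,
    "occlusal_table": Zone.occlusal_incisal,
}


def _fdi_codes(positions: Iterable[int], quadrants: Iterable[int] = (1, 2, 3, 4)) -> frozenset[int]:
    return frozenset(10 * q + p for q in quadrants for p in positions)


class ToothGroupName(str, Enum):
    early_erupting = "early_erupting"
    maxillary_incisors = "maxillary_incisors"
    late_erupting = "late_erupting"


# incisors = positions 1-2, canines = 3, premolars = 4-5,
# first molars = 6, second molars = 7; third molars (8) are never scored.
_TOOTH_GROUPS: dict[ToothGroupName, frozenset[int]] = {
    ToothGroupName.early_erupting: _fdi_codes((1, 2, 6)),
    ToothGroupName.maxillary_incisors: _fdi_codes((1, 2), quadrants=(1, 2)),
    ToothGroupName.late_erupting: _fdi_codes((3, 4, 5, 7)),
}

PERMANENT_FDI_CODES: frozenset[int] = _fdi_codes(range(1, 9))


def tooth_group_members(name: ToothGroupName | str) -> frozenset[int]:
    """FDI codes of the permanent teeth in a named analysis group.

    ``early_erupting`` holds the 8 permanent incisors and 4 first molars
    (12 teeth), ``maxillary_incisors`` the 4 upper incisors (a subset of
    the early group), and ``late_erupting`` the 4 canines, 8 premolars
    and 4 second molars (16 teeth).
    """
    try:
        key = ToothGroupName(name)
    except ValueError:
        raise ValueError(
            f"unknown tooth group {name!r}; expected one of "
            f"{[g.value for g in ToothGroupName]}"
        ) from None
    return _TOOTH_GROUPS[key]


def group_waves(name: ToothGroupName | str, waves: Iterable[int] = DEFAULT_WAVES) -> tuple[int, ...]:
    """Exam waves at which a tooth group is scoreable.

    Late-erupting teeth (canines, premolars, second molars) are not yet
    erupted for most children at the age-9 exam, so that group's
    trajectory starts at the second wave.
    """
    waves = tuple(waves)
    if ToothGroupName(name) is ToothGroupName.late_erupting:
        return waves[1:]
    return waves


def universal_to_fdi(code: int) -> int:
    """Map a Universal (ADA, 1–32) permanent-tooth number to FDI notation."""
    if not 1 <= code <= 32:
        raise ValueError(f"universal tooth number out of range 1-32: {code}")
    if code <= 8:        # upper right, 1..8 = third molar..central incisor
        return 10 + (9 - code)
    if code <= 16:       # upper left, 9..16 = central incisor..third molar
        return 20 + (code - 8)
    if code <= 24:       # lower left, 17..24 = third molar..central incisor
        return 30 + (25 - code)
    return 40 + (code - 24)  # lower right


@dataclass(frozen=True)
class ZoneScore:
    """One examiner's FRI score for one zone of one tooth at one exam."""

    participant_id: str
    exam_age: int
    examiner_id: str
    tooth: int
    zone: Zone
    fri: int
    nonfluoride_opacity: bool = False
    is_primary: bool = True

    def __post_init__(self) -> None:
        if self.fri not in FRI_LEVELS:
            raise ValueError(f"fri must be in {FRI_LEVELS}, got {self.fri}")
        if self.nonfluoride_opacity and self.fri != 0:
            raise ValueError("non-fluoride opacity implies fri = 0")
        if self.tooth not in PERMANENT_FDI_CODES:
            raise ValueError(f"not a permanent-dentition FDI code: {self.tooth}")


class CohortValidationError(ValueError):
    """Raised when exam rows violate the zone-score invariants.

    ``errors`` holds one human-readable message per offending row,
    each naming the (1-based, header-inclusive) file line.
    """

    def __init__(self, errors: list[str]):
        self.errors = errors
        preview = "\n".join(errors[:10])
        more = f"\n... and {len(errors) - 10} more" if len(errors) > 10 else ""
        super().__init__(f"{len(errors)} invalid exam row(s):\n{preview}{more}")


EXAM_COLUMNS = [
    "participant_id",
    "exam_age",
    "examiner_id",
    "tooth",
    "zone",
    "fri",
    "nonfluoride_opacity",
    "is_primary",
]

BLEACHING_COLUMNS = ["participant_id", "interval", "used_bleaching"]


@dataclass
class CohortDataset:
    """All zone scores of a cohort plus participant-level metadata.

    ``scores`` is a long-format frame with one row per
    (participant, exam age, examiner, tooth, zone) observation, columns
    as in :data:`EXAM_COLUMNS`. Duplicate exams — the same
    participant/age/tooth/zone scored by a second examiner — are kept
    for inter-examiner reliability; exactly the rows flagged
    ``is_primary`` enter the severity analyses.

    ``bleaching`` maps participants to reported bleaching/whitening
    product use per inter-exam interval (e.g. ``"9-13"``).
    """

    scores: pd.DataFrame
    bleaching: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=BLEACHING_COLUMNS)
    )
    waves: tuple[int, ...] = DEFAULT_WAVES

    def __post_init__(self) -> None:
        self.scores = _normalize_scores(self.scores)
        self.waves = tuple(sorted(self.waves))

    @property
    def primary(self) -> pd.DataFrame:
        """The one-record-per-zone analysis subset."""
        return self.scores[self.scores["is_primary"]]

    @property
    def participants(self) -> list[str]:
        return sorted(self.scores["participant_id"].unique())

    def duplicate_exam_units(self) -> pd.DataFrame:
        """Zone observations rated by more than one examiner.

        Returns the subset of ``scores`` restricted to
        (participant, age, tooth, zone) units with ≥2 examiner records.
        """
        key = ["participant_id", "exam_age", "tooth", "zone"]
        n_raters = self.scores.groupby(key)["examiner_id"].transform("nunique")
        return self.scores[n_raters >= 2]

    def bleaching_users(self, interval: str | None = None) -> frozenset[str]:
        """Participants who reported bleaching/whitening use.

        With ``interval=None``, "at least once during the study period".
        """
        b = self.bleaching
        if interval is not None:
            b = b[b["interval"] == interval]
        return frozenset(b.loc[b["used_bleaching"].astype(bool), "participant_id"])

    def equals(self, other: "CohortDataset") -> bool:
        key = ["participant_id", "exam_age", "examiner_id", "tooth", "zone"]
        a = self.scores.sort_values(key).reset_index(drop=True)
        b = other.scores.sort_values(key).reset_index(drop=True)
        ba = self.bleaching.sort_values(BLEACHING_COLUMNS).reset_index(drop=True)
        bb = other.bleaching.sort_values(BLEACHING_COLUMNS).reset_index(drop=True)
        return a.equals(b) and ba.equals(bb) and self.waves == other.waves


def _normalize_scores(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    missing = [c for c in EXAM_COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError([f"missing exam columns: {missing}"])
    df["participant_id"] = df["participant_id"].astype(str)
    df["examiner_id"] = df["examiner_id"].astype(str)
    for col in ("exam_age", "tooth", "fri"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype(int)
    df["zone"] = df["zone"].map(lambda z: Zone(z).value if not isinstance(z, Zone) else z.value)
    for col in ("nonfluoride_opacity", "is_primary"):
        df[col] = df[col].astype(bool)
    return df[EXAM_COLUMNS]


def _validate_rows(df: pd.DataFrame, line_offset: int = 2) -> list[str]:
    """Row-addressed invariant violations; line numbers count the header."""
    errors: list[str] = []
    bad_fri = ~df["fri"].isin(FRI_LEVELS)
    bad_tooth = ~df["tooth"].isin(PERMANENT_FDI_CODES)
    bad_opacity = df["nonfluoride_opacity"] & (df["fri"] != 0)
    for idx in df.index[bad_fri]:
        errors.append(f"line {idx + line_offset}: fri={df.at[idx, 'fri']} outside 0-3")
    for idx in df.index[bad_tooth]:
        errors.append(
            f"line {idx + line_offset}: tooth={df.at[idx, 'tooth']} is not a "
            "permanent-dentition FDI code"
        )
    for idx in df.index[bad_opacity]:
        errors.append(
            f"line {idx + line_offset}: nonfluoride_opacity with fri="
            f"{df.at[idx, 'fri']} (opacities are scored 0)"
        )
    # >4 distinct zones per tooth record cannot happen with the zone enum,
    # but duplicated zone rows for the same examiner can:
    key = ["participant_id", "exam_age", "examiner_id", "tooth", "zone"]
    for idx in df.index[df.duplicated(key, keep="first")]:
        errors.append(
            f"line {idx + line_offset}: duplicate zone record for "
            f"{tuple(df.loc[idx, key])}"
        )
    return errors


def read_cohort(
    exam_path,
    bleaching_path=None,
    zone_aliases: Mapping[str, str] | None = None,
    tooth_notation: str = "fdi",
) -> CohortDataset:
    """Read and validate a long-format exam CSV (plus optional bleaching CSV).

    Parameters
    ----------
    exam_path
        CSV with header ``participant_id, exam_age, examiner_id, tooth,
        zone, fri, nonfluoride_opacity, is_primary``.
    bleaching_path
        Optional CSV with header ``participant_id, interval,
        used_bleaching`` (0/1).
    zone_aliases
        Extra ``label -> canonical zone`` entries merged over the
        built-in alias map.
    tooth_notation
        ``"fdi"`` (default) or ``"universal"`` (ADA 1–32, converted on
        input).

    Raises
    ------
    CohortValidationError
        Listing every offending row with its file line number.
    """
    try:
        raw = pd.read_csv(exam_path)
    except pd.errors.ParserError as exc:
        raise CohortValidationError([f"malformed CSV {exam_path}: {exc}"]) from exc
    missing = [c for c in EXAM_COLUMNS if c not in raw.columns]
    if missing:
        raise CohortValidationError([f"{exam_path}: missing columns {missing}"])

    aliases = dict(ZONE_ALIASES)
    if zone_aliases:
        aliases.update({k: Zone(v) for k, v in zone_aliases.items()})
    errors: list[str] = []
    zones = []
    for idx, label in raw["zone"].items():
        z = aliases.get(str(label).strip().lower())
        if z is None:
            errors.append(f"line {idx + 2}: unknown zone label {label!r}")
            zones.append(None)
        else:
            zones.append(z.value)
    raw["zone"] = zones

    for col in ("exam_age", "tooth", "fri"):
        coerced = pd.to_numeric(raw[col], errors="coerce")
        for idx in raw.index[coerced.isna()]:
            errors.append(f"line {idx + 2}: non-numeric {col}={raw.at[idx, col]!r}")
        raw[col] = coerced.fillna(-1).astype(int)
    if tooth_notation == "universal":
        raw["tooth"] = [
            universal_to_fdi(t) if 1 <= t <= 32 else t for t in raw["tooth"]
        ]
    elif tooth_notation != "fdi":
        raise ValueError(f"tooth_notation must be 'fdi' or 'universal', got {tooth_notation!r}")
    raw["nonfluoride_opacity"] = _parse_bool(raw["nonfluoride_opacity"])
    raw["is_primary"] = _parse_bool(raw["is_primary"])

    errors.extend(_validate_rows(raw))
    if errors:
        raise CohortValidationError(sorted(set(errors)))

    bleaching = pd.DataFrame(columns=BLEACHING_COLUMNS)
    if bleaching_path is not None:
        bleaching = pd.read_csv(bleaching_path)
        missing_b = [c for c in BLEACHING_COLUMNS if c not in bleaching.columns]
        if missing_b:
            raise CohortValidationError([f"{bleaching_path}: missing columns {missing_b}"])
        bleaching["participant_id"] = bleaching["participant_id"].astype(str)
        bleaching["used_bleaching"] = _parse_bool(bleaching["used_bleaching"])
        bleaching = bleaching[BLEACHING_COLUMNS]

    waves = tuple(sorted(raw["exam_age"].unique()))
    return CohortDataset(scores=raw, bleaching=bleaching, waves=waves)


def _parse_bool(series: pd.Series) -> pd.Series:
    mapping = {
        "true": True, "false": False, "1": True, "0": False,
        "yes": True, "no": False, "t": True, "f": False,
    }
    return series.map(lambda v: mapping.get(str(v).strip().lower(), bool(v) if isinstance(v, (bool, int)) else v)).astype(bool)


def write_cohort(data: CohortDataset, exam_path, bleaching_path=None) -> None:
    """Write a dataset back to the exam/bleaching CSV layout of :func:`read_cohort`."""
    out = data.scores.copy()
    out["nonfluoride_opacity"] = out["nonfluoride_opacity"].astype(int)
    out["is_primary"] = out["is_primary"].astype(int)
    _to_csv(out, exam_path)
    if bleaching_path is not None:
        b = data.bleaching.copy()
        b["used_bleaching"] = b["used_bleaching"].astype(int)
        _to_csv(b, bleaching_path)


def _to_csv(df: pd.DataFrame, path) -> None:
    if isinstance(path, io.IOBase):
        df.to_csv(path, index=False)
    else:
        df.to_csv(str(path), index=False)
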