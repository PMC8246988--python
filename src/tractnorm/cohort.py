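"""Cohort I/O: demographics + tract-mean-FA tables and hemisphere mapping.

The pipeline consumes two CSV files (comma-separated, UTF-8, header row,
decimal point):

``demographics.csv``
    columns ``subject_id, group, sex, age_years, onset_age_years,
    duration_years, ilae_outcome, hs_present`` — the last five empty for
    controls / when unknown.
``tract_fa.csv``
    columns ``subject_id`` plus the ten tract names in :data:`TRACTS`; cells
    are mean fractional anisotropy, strictly inside (0, 1).

Subjects are canonicalised by sorting on ``subject_id`` so that all seeded
resampling downstream is reproducible regardless of input row order.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DuplicateIdError,
    DurationConsistencyError,
    FABoundsError,
    IdMismatchError,
    MissingColumnError,
    MissingValueError,
    UnknownCategoryError,
)

#: Canonical tract order: bilateral anterior thalamic radiation (ATR),
#: cingulum gyrus (CG), cingulum hippocampus (CH), fornix (F) and uncinate
#: fasciculus (UF).
TRACTS: tuple[str, ...] = (
    "ATR.L", "ATR.R", "CG.L", "CG.R", "CH.L",
    "CH.R", "F.L", "F.R", "UF.L", "UF.R",
)
LEFT_TRACTS: tuple[str, ...] = tuple(t for t in TRACTS if t.endswith(".L"))
RIGHT_TRACTS: tuple[str, ...] = tuple(t for t in TRACTS if t.endswith(".R"))

#: Tolerated rounding slack (years) in duration = age - onset.
DURATION_SLACK_YEARS = 1.0

DEMOGRAPHIC_COLUMNS = (
    "subject_id", "group", "sex", "age_years", "onset_age_years",
    "duration_years", "ilae_outcome", "hs_present",
)


class Group(str, enum.Enum):
    CONTROL = "control"
    LEFT_TLE = "left_tle"
    RIGHT_TLE = "right_tle"


class Sex(str, enum.Enum):
    F = "F"
    M = "M"


class Outcome(str, enum.Enum):
    """ILAE surgical outcome, dichotomised: completely seizure free (1)
    versus not (2+)."""

    ILAE1 = "ILAE1"
    ILAE2PLUS = "ILAE2plus"


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's demographics and clinical factors."""

    subject_id: str
    group: Group
    sex: Sex
    age_years: float
    onset_age_years: float | None = None
    duration_years: float | None = None
    ilae_outcome: Outcome | None = None
    hs_present: bool | None = None

    @property
    def is_patient(self) -> bool:
        return self.group is not Group.CONTROL

    def validate(self) -> None:
        if self.age_years < 0:
            raise DurationConsistencyError(
                f"{self.subject_id}: negative age {self.age_years}")
        if self.group is Group.CONTROL:
            for field in ("onset_age_years", "duration_years",
                          "ilae_outcome", "hs_present"):
                if getattr(self, field) is not None:
                    raise UnknownCategoryError(
                        f"{self.subject_id}: control carries patient field "
                        f"{field!r}")
            return
        if (self.onset_age_years is None) != (self.duration_years is None):
            raise DurationConsistencyError(
                f"{self.subject_id}: onset and duration must be jointly "
                "present or jointly absent")
        if self.onset_age_years is not None:
            if self.onset_age_years < 0 or self.duration_years < 0:
                raise DurationConsistencyError(
                    f"{self.subject_id}: negative onset/duration")
            gap = abs(self.age_years - self.onset_age_years
                      - self.duration_years)
            if gap > DURATION_SLACK_YEARS:
                raise DurationConsistencyError(
                    f"{self.subject_id}: duration {self.duration_years} != "
                    f"age {self.age_years} - onset {self.onset_age_years} "
                    f"(gap {gap:.2f} y exceeds {DURATION_SLACK_YEARS} y)")


@dataclass(frozen=True)
class HemisphereMap:
    """Which tracts count as ipsi-/contralateral for a given laterality.

    For controls there is no epileptogenic focus, so the map carries plain
    ``left_tracts``/``right_tracts`` instead.
    """

    group: Group
    ipsilateral_tracts: tuple[str, ...] | None = None
    contralateral_tracts: tuple[str, ...] | None = None
    left_tracts: tuple[str, ...] = LEFT_TRACTS
    right_tracts: tuple[str, ...] = RIGHT_TRACTS


def hemisphere_map(group: Group | str) -> HemisphereMap:
    """Map a laterality onto its ipsilateral/contralateral tract sets.

    Left-TLE: the five ``.L`` tracts are ipsilateral; right-TLE mirrors it;
    controls get left/right sets with no ipsi/contra labels.
    """
    group = Group(group)
    if group is Group.CONTROL:
        return HemisphereMap(group=group)
    if group is Group.LEFT_TLE:
        return HemisphereMap(group=group, ipsilateral_tracts=LEFT_TRACTS,
                             contralateral_tracts=RIGHT_TRACTS)
    return HemisphereMap(group=group, ipsilateral_tracts=RIGHT_TRACTS,
                         contralateral_tracts=LEFT_TRACTS)


def _parse_optional_float(token, subject_id: str, column: str) -> float | None:
    if token is None or (isinstance(token, float) and np.isnan(token)):
        return None
    s = str(token).strip()
    if s == "":
        return None
    try:
        return float(s)
    except ValueError:
        raise UnknownCategoryError(
            f"{subject_id}: cannot parse {column}={token!r}") from None


def _parse_enum(enum_cls, token, subject_id: str, column: str):
    try:
        return enum_cls(str(token).strip())
    except ValueError:
        raise UnknownCategoryError(
            f"{subject_id}: unknown {column} token {token!r}; expected one "
            f"of {[e.value for e in enum_cls]}") from None


def _check_unique_ids(ids: Sequence[str], what: str) -> None:
    counts = pd.Series(ids).value_counts()
    dups = counts[counts > 1]
    if len(dups):
        raise DuplicateIdError(
            f"duplicate subject_id in {what}: {sorted(dups.index)}")


def read_demographics(path: str | Path) -> list[SubjectRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in DEMOGRAPHIC_COLUMNS if c not in df.columns]
    if missing:
        raise MissingColumnError(f"{path}: missing columns {missing}")
    _check_unique_ids(df["subject_id"].tolist(), "demographics")
    records = []
    for row in df.itertuples(index=False):
        sid = row.subject_id
        group = _parse_enum(Group, row.group, sid, "group")
        sex = _parse_enum(Sex, row.sex, sid, "sex")
        age = _parse_optional_float(row.age_years, sid, "age_years")
        if age is None:
            raise MissingValueError(f"{sid}: age_years is empty")
        outcome = (None if str(row.ilae_outcome).strip() == ""
                   else _parse_enum(Outcome, row.ilae_outcome, sid,
                                    "ilae_outcome"))
        hs_token = str(row.hs_present).strip()
        if hs_token == "":
            hs = None
        elif hs_token in ("True", "true", "1", "yes"):
            hs = True
        elif hs_token in ("False", "false", "0", "no"):
            hs = False
        else:
            raise UnknownCategoryError(
                f"{sid}: unknown hs_present token {hs_token!r}")
        rec = SubjectRecord(
            subject_id=sid, group=group, sex=sex, age_years=age,
            onset_age_years=_parse_optional_float(
                row.onset_age_years, sid, "onset_age_years"),
            duration_years=_parse_optional_float(
                row.duration_years, sid, "duration_years"),
            ilae_outcome=outcome, hs_present=hs,
        )
        rec.validate()
        records.append(rec)
    return sorted(records, key=lambda r: r.subject_id)


def read_fa_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = [c for c in ("subject_id", *TRACTS) if c not in df.columns]
    if missing:
        raise MissingColumnError(f"{path}: missing columns {missing}")
    _check_unique_ids(df["subject_id"].tolist(), "tract_fa")
    df = df.set_index("subject_id")[list(TRACTS)].sort_index()
    for tract in TRACTS:
        col = pd.to_numeric(df[tract], errors="coerce")
        if col.isna().any():
            sid = df.index[col.isna()][0]
            raise MissingValueError(
                f"tract_fa cell ({sid}, {tract}) is missing or non-numeric")
        df[tract] = col.astype(float)
    values = df.to_numpy()
    bad = (values <= 0.0) | (values >= 1.0)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise FABoundsError(
            f"FA out of (0,1) at subject {df.index[i]!r}, tract "
            f"{TRACTS[j]!r}: {values[i, j]}")
    return df


def read_cohort(demographics_path: str | Path,
                fa_path: str | Path) -> tuple[list[SubjectRecord], pd.DataFrame]:
    """Read and cross-validate the demographics and tract-FA tables.

    Returns subject records sorted by id and the FA table reindexed to the
    same order. Any structural defect raises a specific
    :class:`~tractnorm.errors.CohortValidationError` subclass.
    """
    subjects = read_demographics(demographics_path)
    fa = read_fa_table(fa_path)
    demo_ids = [s.subject_id for s in subjects]
    if set(demo_ids) != set(fa.index):
        only_demo = sorted(set(demo_ids) - set(fa.index))
        only_fa = sorted(set(fa.index) - set(demo_ids))
        raise IdMismatchError(
            f"id mismatch between files: only in demographics {only_demo}, "
            f"only in tract_fa {only_fa}")
    return subjects, fa.loc[demo_ids]


def subjects_to_frame(subjects: Iterable[SubjectRecord]) -> pd.DataFrame:
    rows = []
    for s in subjects:
        rows.append({
            "subject_id": s.subject_id,
            "group": s.group.value,
            "sex": s.sex.value,
            "age_years": s.age_years,
            "onset_age_years": "" if s.onset_age_years is None
                               else s.onset_age_years,
            "duration_years": "" if s.duration_years is None
                              else s.duration_years,
            "ilae_outcome": "" if s.ilae_outcome is None
                            else s.ilae_outcome.value,
            "hs_present": "" if s.hs_present is None else s.hs_present,
        })
    return pd.DataFrame(rows, columns=list(DEMOGRAPHIC_COLUMNS))


def write_cohort(subjects: Sequence[SubjectRecord], fa_table: pd.DataFrame,
                 demographics_path: str | Path, fa_path: str | Path) -> None:
    """Write both tables in the interchange dialect (round-trips with
    :func:`read_cohort`)."""
    subjects_to_frame(subjects).to_csv(demographics_path, index=False)
    out = fa_table.loc[[s.subject_id for s in subjects], list(TRACTS)]
    out.to_csv(fa_path, index=True, index_label="subject_id")


def split_by_group(subjects: Sequence[SubjectRecord]):
    """(controls, left-TLE, right-TLE) sub-lists, preserving order."""
    controls = [s for s in subjects if s.group is Group.CONTROL]
    left = [s for s in subjects if s.group is Group.LEFT_TLE]
    right = [s for s in subjects if s.group is Group.RIGHT_TLE]
    return controls, left, right
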