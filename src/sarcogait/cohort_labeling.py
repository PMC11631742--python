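"""Participant metadata and grip-strength based sarcopenia labeling.

Labels are assigned from hand-grip strength (HGS) alone, using the
sex-specific cutoffs applied to the study cohort: a participant is labeled
``sarcopenia`` when HGS is *strictly below* 26 kg (men) or 18 kg (women),
and ``normal`` otherwise.  Values exactly at the cutoff are therefore
``normal``.  Gait speed and appendicular muscle mass may be carried as
optional metadata but never influence the label.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

__all__ = [
    "Sex",
    "Label",
    "HGS_CUTOFF_KG",
    "ParticipantRecord",
    "CohortTable",
    "label_awgs",
    "cohort_summary",
    "read_cohort_csv",
    "write_cohort_csv",
]


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class Label(str, enum.Enum):
    SARCOPENIA = "sarcopenia"
    NORMAL = "normal"


#: Default grip-strength cutoffs in kg, strict less-than comparison.
#: An alternative male cutoff of 28 kg exists in the broader guideline
#: literature; pass ``cutoffs=`` explicitly to use it.
HGS_CUTOFF_KG: Mapping[Sex, float] = {Sex.MALE: 26.0, Sex.FEMALE: 18.0}

_SEX_CODES = {"M": Sex.MALE, "F": Sex.FEMALE}
_SEX_TO_CODE = {v: k for k, v in _SEX_CODES.items()}


def _coerce_sex(sex: Sex | str) -> Sex:
    if isinstance(sex, Sex):
        return sex
    try:
        return Sex(str(sex).lower())
    except ValueError:
        raise ValueError(f"unknown sex {sex!r}; expected 'male' or 'female'") from None


def label_awgs(
    sex: Sex | str,
    hgs_kg: float,
    cutoffs: Mapping[Sex, float] = HGS_CUTOFF_KG,
) -> Label:
    """Label a participant from sex and hand-grip strength.

    Returns :data:`Label.SARCOPENIA` iff ``hgs_kg`` is strictly below the
    sex-specific cutoff (default 26 kg male / 18 kg female), else
    :data:`Label.NORMAL`.

    Raises
    ------
    ValueError
        If ``hgs_kg`` is negative or ``sex`` is not male/female.
    """
    sex = _coerce_sex(sex)
    hgs_kg = float(hgs_kg)
    if hgs_kg < 0:
        raise ValueError(f"hgs_kg must be non-negative, got {hgs_kg}")
    return Label.SARCOPENIA if hgs_kg < cutoffs[sex] else Label.NORMAL


@dataclass(frozen=True)
class ParticipantRecord:
    """One participant: identity, sex, age, grip strength and class label.

    ``hgs_kg`` is the mean of three dynamometer trials.  ``label`` may be
    ``None`` (unassigned); once assigned it must equal
    ``label_awgs(sex, hgs_kg)``.
    """

    participant_id: str
    sex: Sex
    age_years: int
    hgs_kg: float
    label: Label | None = None
    extra: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "sex", _coerce_sex(self.sex))
        if self.age_years <= 0:
            raise ValueError(f"age_years must be positive, got {self.age_years}")
        if self.hgs_kg < 0:
            raise ValueError(f"hgs_kg must be non-negative, got {self.hgs_kg}")
        if self.label is not None and not isinstance(self.label, Label):
            object.__setattr__(self, "label", Label(str(self.label).lower()))

    def with_label(self, cutoffs: Mapping[Sex, float] = HGS_CUTOFF_KG) -> "ParticipantRecord":
        return replace(self, label=label_awgs(self.sex, self.hgs_kg, cutoffs))


class CohortTable:
    """Ordered collection of participant records with unique ids."""

    def __init__(self, records: Iterable[ParticipantRecord]):
        self.records: list[ParticipantRecord] = list(records)
        ids = [r.participant_id for r in self.records]
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        if dupes:
            raise ValueError(f"duplicate participant_ids: {dupes}")
        for r in self.records:
            if r.label is not None and r.label != label_awgs(r.sex, r.hgs_kg):
                raise ValueError(
                    f"participant {r.participant_id}: stored label {r.label.value} "
                    f"inconsistent with grip-strength rule"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ParticipantRecord]:
        return iter(self.records)

    def __getitem__(self, pid: str) -> ParticipantRecord:
        for r in self.records:
            if r.participant_id == pid:
                return r
        raise KeyError(pid)

    def labeled(self, cutoffs: Mapping[Sex, float] = HGS_CUTOFF_KG) -> "CohortTable":
        """Return a copy with every record labeled by the grip-strength rule."""
        return CohortTable(r.with_label(cutoffs) for r in self.records)

    def ids_by_label(self) -> dict[Label, list[str]]:
        out: dict[Label, list[str]] = {Label.SARCOPENIA: [], Label.NORMAL: []}
        unlabeled = [r.participant_id for r in self.records if r.label is None]
        if unlabeled:
            raise ValueError(f"unlabeled participants: {unlabeled}")
        for r in self.records:
            out[r.label].append(r.participant_id)
        return out


def cohort_summary(cohort: CohortTable) -> dict:
    """Counts by sex, label, and decade age band.  All records must be labeled."""
    unlabeled = [r.participant_id for r in cohort if r.label is None]
    if unlabeled:
        raise ValueError(f"unlabeled participants: {unlabeled}")
    by_sex = {s.value: 0 for s in Sex}
    by_label = {l.value: 0 for l in Label}
    by_age_band: dict[str, int] = {}
    for r in cohort:
        by_sex[r.sex.value] += 1
        by_label[r.label.value] += 1
        band = f"{10 * (r.age_years // 10)}s"
        by_age_band[band] = by_age_band.get(band, 0) + 1
    return {
        "total": len(cohort),
        "by_sex": by_sex,
        "by_label": by_label,
        "by_age_band": dict(sorted(by_age_band.items())),
    }


def read_cohort_csv(path: str | Path) -> CohortTable:
    """Read ``participant_id,sex,age_years,hgs_kg[,label]`` (sex as M/F)."""
    df = pd.read_csv(path, dtype={"participant_id": str})
    required = {"participant_id", "sex", "age_years", "hgs_kg"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        sex = _SEX_CODES.get(str(row.sex).strip().upper())
        if sex is None:
            raise ValueError(f"unknown sex code {row.sex!r} (expected M or F)")
        label = None
        if "label" in df.columns and isinstance(row.label, str) and row.label:
            label = Label(row.label.lower())
        records.append(
            ParticipantRecord(
                participant_id=str(row.participant_id),
                sex=sex,
                age_years=int(row.age_years),
                hgs_kg=float(row.hgs_kg),
                label=label,
            )
        )
    return CohortTable(records)


def write_cohort_csv(cohort: CohortTable, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in cohort],
            "sex": [_SEX_TO_CODE[r.sex] for r in cohort],
            "age_years": [r.age_years for r in cohort],
            "hgs_kg": [r.hgs_kg for r in cohort],
            "label": [r.label.value if r.label else "" for r in cohort],
        }
    )
    df.to_csv(path, index=False)
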