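"""Schema, validation and CSV round-trip for the 25-item vulnerability questionnaire.

The instrument combines three short forms -- five Outcome Questionnaire (OQ)
items answered on a 0..4 frequency scale, six Depressive Experiences
Questionnaire (DEQ) items on a 1..7 agreement scale, and fourteen Reasons for
Living (RFL) items on a 1..6 importance scale -- plus eight sociodemographic
fields and a suicidal-behavior status with attempt severity.  Records are
stored one row per patient in plain CSV; answers are kept as printed answer
positions (reverse-keying is a scoring concern, handled in :mod:`.features`).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

OQ_ITEMS = (3, 8, 13, 24, 31)
DEQ_ITEMS = (3, 16, 19, 48, 56, 62)
RFL_ITEMS = (2, 5, 10, 12, 14, 17, 19, 20, 22, 24, 25, 40, 45, 50)

OQ_RANGE = (0, 4)
DEQ_RANGE = (1, 7)
RFL_RANGE = (1, 6)

DIAGNOSES = (
    "mild_depressive",
    "moderate_depressive",
    "major_depressive",
    "bipolar",
    "adjustment",
    "anxiety",
    "mixed_episode",
    "dysthymia",
    "other",
)
CHILDREN = ("0", "1", "2", "3", "4", "5+")
GENDERS = ("woman", "man", "other")
SCHOOLING = ("basic", "secondary", "technical", "university")
COHABITATION = ("alone", "friends", "couple", "family")
MARITAL_STATUS = ("single", "married", "separated", "widow", "free_union")
OCCUPATIONS = ("employed", "student", "unemployed", "housewife", "retired/not_working")
SB_STATUS = ("none", "ideation", "attempt_low_severity", "attempt_high_severity")

#: Age bands as printed on the instrument itself (boundary values go to the
#: lower band, i.e. bands are left-closed).
AGE_BANDS_INSTRUMENT = ("18-28", "28-38", "38-48", "48-58", "58-68", "68-78", ">78")
#: Age bands matching the validation study's descriptive tables (enrollment
#: started at 14); selectable because the two published codings disagree.
AGE_BANDS_STUDY = ("14-19", "20-29", "30-39", "40-49", "50-59", "60+")

AGE_BAND_SETS = {"instrument": AGE_BANDS_INSTRUMENT, "study": AGE_BANDS_STUDY}

SB_POSITIVE = frozenset({"ideation", "attempt_low_severity", "attempt_high_severity"})

WITH_SB = "with_sb"
WITHOUT_SB = "without_sb"


class SchemaError(ValueError):
    """A cohort file is missing a required column."""


class ValidationError(ValueError):
    """A record violates the instrument schema (bad range or category)."""


def _item_columns() -> list[str]:
    cols = [f"oq_{i}" for i in OQ_ITEMS]
    cols += [f"deq_{i}" for i in DEQ_ITEMS]
    cols += [f"rfl_{i}" for i in RFL_ITEMS]
    return cols


DEMOGRAPHIC_FIELDS = (
    "diagnosis",
    "children",
    "gender",
    "age_band",
    "schooling",
    "cohabitation",
    "marital_status",
    "occupation",
)

COLUMNS = ("patient_id", *_item_columns(), *DEMOGRAPHIC_FIELDS, "sb_status")

_CATEGORY_SETS = {
    "diagnosis": DIAGNOSES,
    "children": CHILDREN,
    "gender": GENDERS,
    "schooling": SCHOOLING,
    "cohabitation": COHABITATION,
    "marital_status": MARITAL_STATUS,
    "occupation": OCCUPATIONS,
    "sb_status": SB_STATUS,
}


@dataclass
class PatientRecord:
    """One participant: raw answer positions, demographics and SB status."""

    patient_id: str
    oq_items: dict[int, int]
    deq_items: dict[int, int]
    rfl_items: dict[int, int]
    diagnosis: str
    children: str
    gender: str
    age_band: str
    schooling: str
    cohabitation: str
    marital_status: str
    occupation: str
    sb_status: str

    def validate(self, age_bands: Sequence[str] = AGE_BANDS_INSTRUMENT) -> None:
        """Raise :class:`ValidationError` on the first schema violation."""
        for name, items, declared, (lo, hi) in (
            ("oq", self.oq_items, OQ_ITEMS, OQ_RANGE),
            ("deq", self.deq_items, DEQ_ITEMS, DEQ_RANGE),
            ("rfl", self.rfl_items, RFL_ITEMS, RFL_RANGE),
        ):
            if set(items) != set(declared):
                raise ValidationError(
                    f"{self.patient_id}: {name} items {sorted(items)} != declared {sorted(declared)}"
                )
            for item, ans in items.items():
                if not isinstance(ans, (int,)) or isinstance(ans, bool) or not lo <= ans <= hi:
                    raise ValidationError(
                        f"{self.patient_id}: {name}_{item}={ans!r} outside {lo}..{hi}"
                    )
        for fld, allowed in _CATEGORY_SETS.items():
            value = getattr(self, fld)
            if value not in allowed:
                raise ValidationError(f"{self.patient_id}: {fld}={value!r} not in {allowed}")
        if self.age_band not in age_bands:
            raise ValidationError(
                f"{self.patient_id}: age_band={self.age_band!r} not in {tuple(age_bands)}"
            )

    def to_row(self) -> dict[str, object]:
        row: dict[str, object] = {"patient_id": self.patient_id}
        row.update({f"oq_{i}": self.oq_items[i] for i in OQ_ITEMS})
        row.update({f"deq_{i}": self.deq_items[i] for i in DEQ_ITEMS})
        row.update({f"rfl_{i}": self.rfl_items[i] for i in RFL_ITEMS})
        for fld in DEMOGRAPHIC_FIELDS:
            row[fld] = getattr(self, fld)
        row["sb_status"] = self.sb_status
        return row

    @classmethod
    def from_row(cls, row: Mapping[str, object]) -> "PatientRecord":
        def as_int(col: str) -> int:
            v = row[col]
            f = float(v)
            i = int(f)
            if i != f:
                raise ValidationError(f"{row.get('patient_id')}: {col}={v!r} is not an integer")
            return i

        return cls(
            patient_id=str(row["patient_id"]),
            oq_items={i: as_int(f"oq_{i}") for i in OQ_ITEMS},
            deq_items={i: as_int(f"deq_{i}") for i in DEQ_ITEMS},
            rfl_items={i: as_int(f"rfl_{i}") for i in RFL_ITEMS},
            **{fld: str(row[fld]) for fld in DEMOGRAPHIC_FIELDS},
            sb_status=str(row["sb_status"]),
        )


def derive_sb_group(record: PatientRecord) -> str:
    """Binary group label: any ideation or attempt in the window counts as SB."""
    return WITH_SB if record.sb_status in SB_POSITIVE else WITHOUT_SB


def resolve_age_bands(age_bands: str | Sequence[str]) -> tuple[str, ...]:
    if isinstance(age_bands, str):
        try:
            return AGE_BAND_SETS[age_bands]
        except KeyError:
            raise ValueError(f"unknown age band set {age_bands!r}; use {sorted(AGE_BAND_SETS)}")
    return tuple(age_bands)


def read_cohort(
    path: str | Path,
    strict: bool = True,
    age_bands: str | Sequence[str] = "instrument",
) -> list[PatientRecord]:
    """Read a cohort CSV into validated :class:`PatientRecord` objects.

    In strict mode the first invalid record raises; otherwise invalid records
    are dropped with a logged warning and a final count.
    """
    bands = resolve_age_bands(age_bands)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    records: list[PatientRecord] = []
    dropped = 0
    for _, row in frame.iterrows():
        try:
            rec = PatientRecord.from_row(row)
            rec.validate(age_bands=bands)
        except (ValidationError, ValueError) as exc:
            if strict:
                if isinstance(exc, ValidationError):
                    raise
                raise ValidationError(str(exc)) from exc
            dropped += 1
            logger.warning("dropping invalid record: %s", exc)
            continue
        records.append(rec)
    if dropped:
        logger.warning("read_cohort: dropped %d invalid record(s) from %s", dropped, path)
    return records


def write_cohort(records: Iterable[PatientRecord], path: str | Path) -> None:
    """Write records as CSV with the canonical stable column order."""
    rows = [r.to_row() for r in records]
    frame = pd.DataFrame(rows, columns=list(COLUMNS))
    frame.to_csv(path, index=False)


def schema_document() -> dict:
    """Machine-readable column dictionary for the cohort CSV format."""
    doc: dict[str, object] = {
        "format": "csv",
        "encoding": "utf-8",
        "columns": list(COLUMNS),
        "items": {
            "oq": {"ids": list(OQ_ITEMS), "range": list(OQ_RANGE),
                   "scale": "answer position, Never..Almost always"},
            "deq": {"ids": list(DEQ_ITEMS), "range": list(DEQ_RANGE),
                    "scale": "Totally agree 1 .. Totally disagree 7"},
            "rfl": {"ids": list(RFL_ITEMS), "range": list(RFL_RANGE),
                    "scale": "Not important 1 .. Extremely important 6"},
        },
        "categories": {k: list(v) for k, v in _CATEGORY_SETS.items()},
        "age_band_sets": {k: list(v) for k, v in AGE_BAND_SETS.items()},
        "sb_positive": sorted(SB_POSITIVE),
    }
    return doc


def write_schema(path: str | Path) -> None:
    Path(path).write_text(json.dumps(schema_document(), indent=2))
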