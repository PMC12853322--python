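"""Domain records for liver-transplant waitlist candidates.

Canonical storage units follow registry reporting conventions: creatinine,
urea and bilirubin in mg/dL, sodium in mmol/L, albumin in g/dL.  Any
formula-specific unit conversion (e.g. the GFR equation wants creatinine in
umol/L) happens inside the score functions, so a single validated record
feeds every score.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence


class ValidationError(ValueError):
    """A record violates a physiological or structural constraint."""


class SchemaError(ValueError):
    """A cohort file is missing mandatory columns."""


class ConversionError(ValueError):
    """Unknown quantity/unit pair for a unit conversion."""


class AscitesGrade(str, Enum):
    NONE = "none"
    MILD = "mild"
    MODERATE_SEVERE = "moderate_severe"


class Sex(str, Enum):
    FEMALE = "female"
    MALE = "male"


class Disposition(str, Enum):
    """Raw waitlist disposition at the end of observation."""

    DEATH_OR_DELISTING_SICK = "death_or_delisting_sick"
    TRANSPLANTED = "transplanted"
    REMOVED_OTHER = "removed_other"
    ADMINISTRATIVELY_CENSORED = "administratively_censored"


#: Multiplicative factors taking mg/dL to the alternative reporting unit.
CREATININE_MGDL_PER_UMOLL = 88.4   # 1 mg/dL creatinine = 88.4 umol/L
UREA_MGDL_TO_MMOLL = 0.1665        # 1 mg/dL urea = 0.1665 mmol/L

_CONVERSIONS = {
    ("creatinine", "mg/dL", "umol/L"): CREATININE_MGDL_PER_UMOLL,
    ("creatinine", "umol/L", "mg/dL"): 1.0 / CREATININE_MGDL_PER_UMOLL,
    ("urea", "mg/dL", "mmol/L"): UREA_MGDL_TO_MMOLL,
    ("urea", "mmol/L", "mg/dL"): 1.0 / UREA_MGDL_TO_MMOLL,
}


def convert_units(value: float, quantity: str, from_unit: str, to_unit: str) -> float:
    """Convert a lab value between reporting units.

    Supported: creatinine mg/dL <-> umol/L (factor 88.4) and urea
    mg/dL <-> mmol/L (factor 0.1665).  Identity conversions are allowed.
    """
    if from_unit == to_unit:
        return value
    key = (quantity, from_unit, to_unit)
    if key not in _CONVERSIONS:
        raise ConversionError(f"no conversion for {quantity}: {from_unit} -> {to_unit}")
    return value * _CONVERSIONS[key]


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


def _finite(x: float) -> bool:
    return isinstance(x, (int, float)) and math.isfinite(x)


@dataclass(frozen=True)
class PatientRecord:
    """One candidate's demographics, labs and ascites grade at listing.

    All numeric fields must be finite and within physiological bounds;
    violations raise :class:`ValidationError` (no silent clamping — clamping
    is a property of score formulas, not of stored data).  ``albumin`` may be
    ``None``; such records are retained but excluded from MELD 3.0.
    """

    patient_id: str
    age: float                  # years, 18-100
    sex: Sex
    creatinine: float           # mg/dL
    urea: float                 # mg/dL
    bilirubin: float            # mg/dL
    inr: float                  # dimensionless
    sodium: float               # mmol/L, 100-180
    ascites: AscitesGrade
    albumin: float | None = None  # g/dL, optional

    def __post_init__(self) -> None:
        _check(_finite(self.age) and 18.0 <= self.age <= 100.0,
               f"age {self.age!r} outside [18, 100]")
        for name in ("creatinine", "urea", "bilirubin", "inr"):
            v = getattr(self, name)
            _check(_finite(v) and v > 0.0, f"{name} {v!r} must be finite and > 0")
        _check(_finite(self.sodium) and 100.0 <= self.sodium <= 180.0,
               f"sodium {self.sodium!r} outside [100, 180] mmol/L")
        if self.albumin is not None:
            _check(_finite(self.albumin) and self.albumin > 0.0,
                   f"albumin {self.albumin!r} must be finite and > 0")
        _check(isinstance(self.sex, Sex), "sex must be a Sex enum member")
        _check(isinstance(self.ascites, AscitesGrade),
               "ascites must be an AscitesGrade enum member")

    @property
    def has_albumin(self) -> bool:
        return self.albumin is not None


@dataclass(frozen=True)
class OutcomeRecord:
    """Raw waitlist disposition: what happened and after how many days."""

    patient_id: str
    days_observed: int
    disposition: Disposition

    def __post_init__(self) -> None:
        _check(isinstance(self.days_observed, int) and self.days_observed >= 0,
               f"days_observed {self.days_observed!r} must be an integer >= 0")
        _check(isinstance(self.disposition, Disposition),
               "disposition must be a Disposition enum member")


@dataclass(frozen=True)
class PrimaryOutcome:
    """90-day right-censored reduction of an :class:`OutcomeRecord`.

    ``event`` is True for death or delisting for clinical deterioration
    within the first 90 days (day 90 inclusive); transplant and other
    removals right-censor at their own time, everything else is
    administratively censored at day 90.
    """

    time: float   # days, in (0, 90]
    event: bool

    def __post_init__(self) -> None:
        _check(0.0 < self.time <= 90.0, f"time {self.time!r} outside (0, 90]")


HORIZON_DAYS = 90.0
#: Zero-day observations are shifted here so survival machinery that needs
#: strictly positive times stays usable.
ZERO_DAY_TIME = 0.5


def to_primary_outcome(rec: OutcomeRecord) -> PrimaryOutcome:
    """Reduce a raw disposition to the 90-day primary outcome.

    Death/delisting-for-sickness at <= 90 days is an event at that time;
    transplant or other removal before day 90 censors at that time; anything
    else (including events recorded after day 90) censors at day 90.
    """
    t = float(rec.days_observed)
    if t == 0.0:
        t = ZERO_DAY_TIME
    if (rec.disposition is Disposition.DEATH_OR_DELISTING_SICK
            and rec.days_observed <= HORIZON_DAYS):
        return PrimaryOutcome(time=min(t, HORIZON_DAYS), event=True)
    if (rec.disposition in (Disposition.TRANSPLANTED, Disposition.REMOVED_OTHER)
            and rec.days_observed < HORIZON_DAYS):
        return PrimaryOutcome(time=t, event=False)
    return PrimaryOutcome(time=HORIZON_DAYS, event=False)


# ---------------------------------------------------------------------------
# CSV input/output
# ---------------------------------------------------------------------------

CANONICAL_COLUMNS = (
    "patient_id", "age", "sex", "creatinine_mgdl", "urea_mgdl",
    "bilirubin_mgdl", "inr", "sodium_mmoll", "albumin_gdl", "ascites",
    "days_observed", "disposition",
)

_OPTIONAL_COLUMNS = {"albumin_gdl"}


@dataclass(frozen=True)
class SchemaOptions:
    """Column-name mapping and unit declarations for cohort CSVs.

    ``columns`` maps canonical names to the names actually present in the
    file.  Units may be declared for creatinine (mg/dL or umol/L) and urea
    (mg/dL or mmol/L); values are converted to canonical mg/dL on read.
    """

    columns: Mapping[str, str] = field(default_factory=dict)
    creatinine_unit: str = "mg/dL"
    urea_unit: str = "mg/dL"

    def resolve(self, canonical: str) -> str:
        return self.columns.get(canonical, canonical)


@dataclass(frozen=True)
class RowReject:
    row_number: int   # 1-based data-row index (header not counted)
    reason: str


@dataclass
class CohortReadResult:
    records: list[tuple[PatientRecord, OutcomeRecord]]
    rejects: list[RowReject]


def _parse_float(raw: str, name: str) -> float:
    try:
        v = float(raw)
    except (TypeError, ValueError):
        raise ValidationError(f"unparsable {name}") from None
    if not math.isfinite(v):
        raise ValidationError(f"unparsable {name}")
    return v


def read_cohort(path: str | Path,
                schema_options: SchemaOptions | None = None) -> CohortReadResult:
    """Read and validate a cohort CSV.

    Returns validated ``(PatientRecord, OutcomeRecord)`` pairs in canonical
    units plus a reject list with row numbers and reasons.  Missing mandatory
    columns raise :class:`SchemaError`; bad rows are collected, not raised
    (complete-case policy: a row missing any score input other than albumin
    is rejected; a row missing only albumin is kept with ``albumin=None``).
    """
    opts = schema_options or SchemaOptions()
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, no header row")
        missing = [c for c in CANONICAL_COLUMNS
                   if c not in _OPTIONAL_COLUMNS and opts.resolve(c) not in reader.fieldnames]
        if missing:
            raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
        has_albumin_col = opts.resolve("albumin_gdl") in reader.fieldnames

        records: list[tuple[PatientRecord, OutcomeRecord]] = []
        rejects: list[RowReject] = []
        for i, row in enumerate(reader, start=1):
            try:
                records.append(_parse_row(row, opts, has_albumin_col))
            except ValidationError as exc:
                rejects.append(RowReject(row_number=i, reason=str(exc)))
    return CohortReadResult(records=records, rejects=rejects)


def _parse_row(row: Mapping[str, str], opts: SchemaOptions,
               has_albumin_col: bool) -> tuple[PatientRecord, OutcomeRecord]:
    def get(canonical: str) -> str:
        raw = row.get(opts.resolve(canonical))
        return "" if raw is None else raw.strip()

    pid = get("patient_id")
    if not pid:
        raise ValidationError("missing patient_id")

    age = _parse_float(get("age"), "age")
    creat = convert_units(_parse_float(get("creatinine_mgdl"), "creatinine"),
                          "creatinine", opts.creatinine_unit, "mg/dL")
    urea = convert_units(_parse_float(get("urea_mgdl"), "urea"),
                         "urea", opts.urea_unit, "mg/dL")
    bili = _parse_float(get("bilirubin_mgdl"), "bilirubin")
    inr = _parse_float(get("inr"), "inr")
    sodium = _parse_float(get("sodium_mmoll"), "sodium")

    alb_raw = get("albumin_gdl") if has_albumin_col else ""
    albumin = _parse_float(alb_raw, "albumin") if alb_raw else None

    sex_raw = get("sex").lower()
    sex_map = {"female": Sex.FEMALE, "f": Sex.FEMALE, "male": Sex.MALE, "m": Sex.MALE}
    if sex_raw not in sex_map:
        raise ValidationError(f"unparsable sex {sex_raw!r}")
    asc_raw = get("ascites").lower().replace("-", "_").replace(" ", "_")
    try:
        ascites = AscitesGrade(asc_raw)
    except ValueError:
        raise ValidationError(f"unparsable ascites grade {asc_raw!r}") from None

    days_raw = get("days_observed")
    try:
        days = int(days_raw)
    except (TypeError, ValueError):
        raise ValidationError("unparsable days_observed") from None
    try:
        disp = Disposition(get("disposition").lower())
    except ValueError:
        raise ValidationError(f"unparsable disposition {get('disposition')!r}") from None

    patient = PatientRecord(patient_id=pid, age=age, sex=sex_map[sex_raw],
                            creatinine=creat, urea=urea, bilirubin=bili, inr=inr,
                            sodium=sodium, albumin=albumin, ascites=ascites)
    outcome = OutcomeRecord(patient_id=pid, days_observed=days, disposition=disp)
    return patient, outcome


def _format_number(x: float) -> str:
    return repr(float(x))


def write_cohort(records: Iterable[tuple[PatientRecord, OutcomeRecord]],
                 path: str | Path) -> None:
    """Write records to a canonical-format CSV (round-trip safe with
    :func:`read_cohort`: floats use ``repr`` so values survive bit-exactly)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CANONICAL_COLUMNS)
        for patient, outcome in records:
            writer.writerow([
                patient.patient_id,
                _format_number(patient.age),
                patient.sex.value,
                _format_number(patient.creatinine),
                _format_number(patient.urea),
                _format_number(patient.bilirubin),
                _format_number(patient.inr),
                _format_number(patient.sodium),
                "" if patient.albumin is None else _format_number(patient.albumin),
                patient.ascites.value,
                str(outcome.days_observed),
                outcome.disposition.value,
            ])


def records_to_frame(records: Sequence[tuple[PatientRecord, OutcomeRecord]]):
    """Tabulate record pairs as a pandas DataFrame in canonical columns,
    with the 90-day reduction appended as ``time``/``event`` columns."""
    import pandas as pd

    rows = []
    for patient, outcome in records:
        po = to_primary_outcome(outcome)
        rows.append({
            "patient_id": patient.patient_id,
            "age": patient.age,
            "sex": patient.sex.value,
            "creatinine_mgdl": patient.creatinine,
            "urea_mgdl": patient.urea,
            "bilirubin_mgdl": patient.bilirubin,
            "inr": patient.inr,
            "sodium_mmoll": patient.sodium,
            "albumin_gdl": patient.albumin,
            "ascites": patient.ascites.value,
            "days_observed": outcome.days_observed,
            "disposition": outcome.disposition.value,
            "time": po.time,
            "event": po.event,
        })
    return pd.DataFrame(rows)
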