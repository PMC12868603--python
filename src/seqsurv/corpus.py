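"""Data model and pre-processing for longitudinal coded EHR.

Turns raw patient records — demographics, dated diagnosis / medication /
procedure encounters, measurements, and outcome dates — into the inputs the
downstream models consume: harmonised code vocabularies, a uniformly sampled
index date within each patient's eligibility window, token sequences (code /
age / visit-position channels terminated by a PREDICT token), and censored
survival labels.

Conventions
-----------
* Diagnoses are harmonised to level-4 ICD-10: the three-character category
  plus at most one character after the decimal point (``I50.19`` → ``I50.1``).
* Medications are harmonised to BNF section level (first four digits) where a
  BNF mapping exists, otherwise to the virtual therapeutic moiety (VTM) code;
  unmappable products become ``UNK`` with a logged warning.
* Only codes carried by at least ``min_prevalence`` of patients enter the
  vocabulary (default 0.1%).
* Time-to-event is measured in months of 30.4375 days.
* Birth dates are taken as July 1 of the recorded birth year, the convention
  for year-of-birth-only pseudonymised records.
"""

from __future__ import annotations

import csv
import json
import logging
import math
import re
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

DAYS_PER_MONTH = 30.4375

MODALITIES = ("diagnosis", "medication", "procedure")

#: special vocabulary tokens, ids fixed for reproducibility
PAD, UNK, PREDICT = "[PAD]", "[UNK]", "[PREDICT]"
SPECIAL_TOKENS = (PAD, UNK, PREDICT)

MEASUREMENT_VARIABLES = ("SBP", "BMI", "creatinine", "sodium", "smoking", "NYHA")
SMOKING_LEVELS = ("no", "ex", "yes")
NYHA_LEVELS = ("I", "II", "III", "IV")


class MappingError(ValueError):
    """A raw code does not match the expected vocabulary shape."""


class PatientExcluded(Exception):
    """The patient cannot contribute an index date (empty eligibility window)."""


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

@dataclass
class Encounter:
    patient_id: str
    code: str
    modality: str
    date: date


@dataclass
class MeasurementRecord:
    patient_id: str
    variable: str
    value: object  # float for numeric variables, str for smoking / NYHA
    date: date


@dataclass
class PatientRecord:
    patient_id: str
    sex: str                      # "female" | "male"
    birth_year: int
    site: str                     # practice / hospital identifier
    registration_start: date
    first_hf_date: date
    hf_subtype: str = "unknown"   # "preserved" | "reduced" | "unknown"
    death_date: date | None = None
    last_followup_date: date | None = None
    encounters: list[Encounter] = field(default_factory=list)
    measurements: list[MeasurementRecord] = field(default_factory=list)

    @property
    def birth_date(self) -> date:
        return date(self.birth_year, 7, 1)

    def age_years(self, on: date) -> float:
        return (on - self.birth_date).days / 365.25


@dataclass
class SurvivalLabel:
    time: float   # months from baseline
    event: int    # 1 = death observed, 0 = censored


@dataclass(frozen=True)
class TokenSequence:
    code_ids: np.ndarray       # (max_len,) int
    age_ids: np.ndarray        # (max_len,) int
    position_ids: np.ndarray   # (max_len,) int visit numbers; 0 = padding
    attention_mask: np.ndarray  # (max_len,) 1 for real tokens
    predict_index: int         # slot of the terminal PREDICT token
    codes: tuple = ()          # code string per slot ("" for PAD), for attribution

    def __len__(self) -> int:
        return int(self.attention_mask.sum())


# ---------------------------------------------------------------------------
# code mapping
# ---------------------------------------------------------------------------

_ICD10_RE = re.compile(r"^([A-Z][0-9][0-9A-Z])\.?([0-9A-Z]{0,4})$")


def map_diagnosis_code(raw: str) -> str:
    """Truncate an ICD-10 code to level 4: category plus one subdigit.

    Both dotted (``N29.9``) and undotted (``I5019``) dialects are accepted;
    output is dot-normalised. Category-only codes pass through.
    """
    m = _ICD10_RE.match(raw.strip().upper())
    if not m:
        raise MappingError(f"not an ICD-10 shaped code: {raw!r}")
    category, ext = m.groups()
    return f"{category}.{ext[0]}" if ext else category


def map_medication_code(raw: str, bnf_map: dict[str, str],
                        vtm_map: dict[str, str]) -> str:
    """Map a product code to BNF section level, falling back to VTM, then UNK."""
    if raw in bnf_map:
        return bnf_map[raw][:4]
    if raw in vtm_map:
        return vtm_map[raw]
    logger.warning("product code %r absent from BNF and VTM maps; mapped to UNK", raw)
    return UNK


def load_mapping_table(path: str | Path) -> dict[str, str]:
    """Two-column CSV (source_code, target_code) → dict."""
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if len(header) != 2:
            raise MappingError(f"mapping table {path} must have two columns")
        return {row[0]: row[1] for row in reader if row}


# ---------------------------------------------------------------------------
# vocabulary
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Vocabulary:
    code_to_id: dict
    age_min: int
    age_max: int
    max_position: int

    # -- code channel --
    @property
    def n_codes(self) -> int:
        return len(self.code_to_id)

    def code_id(self, code: str) -> int:
        return self.code_to_id.get(code, self.code_to_id[UNK])

    @property
    def pad_id(self) -> int:
        return self.code_to_id[PAD]

    @property
    def unk_id(self) -> int:
        return self.code_to_id[UNK]

    @property
    def predict_id(self) -> int:
        return self.code_to_id[PREDICT]

    # -- age channel: id 0 reserved for PAD/out-of-range --
    @property
    def n_ages(self) -> int:
        return self.age_max - self.age_min + 2

    def age_id(self, age_years: float) -> int:
        y = int(math.floor(age_years))
        if y < self.age_min or y > self.age_max:
            return 0
        return y - self.age_min + 1

    # -- position channel: visit numbers 1..max_position, 0 = PAD --
    @property
    def n_positions(self) -> int:
        return self.max_position + 1

    def content_hash(self) -> str:
        import hashlib
        payload = json.dumps([sorted(self.code_to_id.items()),
                              self.age_min, self.age_max, self.max_position])
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_json(self) -> dict:
        return {"code_to_id": self.code_to_id, "age_min": self.age_min,
                "age_max": self.age_max, "max_position": self.max_position}

    @classmethod
    def from_json(cls, d: dict) -> "Vocabulary":
        return cls(code_to_id=dict(d["code_to_id"]), age_min=int(d["age_min"]),
                   age_max=int(d["age_max"]), max_position=int(d["max_position"]))


def build_vocabulary(records: list[PatientRecord],
                     min_prevalence: float = 0.001) -> Vocabulary:
    """Vocabulary over codes carried by ≥ ceil(min_prevalence·n) patients.

    Special tokens are always present. The age channel covers the integer-year
    range observed across encounters (padded a little so baseline ages fit);
    position ids cover 1..max visits + 1 (the PREDICT slot's visit number).
    """
    if not records:
        raise ValueError("cannot build a vocabulary from an empty cohort")
    n = len(records)
    carriers: dict[str, set] = {}
    ages: list[int] = []
    max_visits = 1
    for rec in records:
        seen_dates = {e.date for e in rec.encounters}
        max_visits = max(max_visits, len(seen_dates))
        for enc in rec.encounters:
            carriers.setdefault(enc.code, set()).add(rec.patient_id)
            ages.append(int(math.floor(rec.age_years(enc.date))))
    threshold = math.ceil(min_prevalence * n)
    kept = sorted(c for c, pats in carriers.items() if len(pats) >= threshold)
    code_to_id = {tok: i for i, tok in enumerate(SPECIAL_TOKENS)}
    for code in kept:
        code_to_id[code] = len(code_to_id)
    if ages:
        age_min, age_max = min(ages), max(ages) + 5
    else:
        age_min, age_max = 40, 110
    return Vocabulary(code_to_id=code_to_id, age_min=age_min, age_max=age_max,
                      max_position=max_visits + 1)


# ---------------------------------------------------------------------------
# index date, sequences, labels
# ---------------------------------------------------------------------------

def select_baseline(patient: PatientRecord, study_end: date,
                    rng: np.random.Generator) -> date:
    """Sample one calendar day uniformly from the patient's eligibility window.

    The window runs from the first HF diagnosis to the earliest of death, loss
    to follow-up and the administrative study end (exclusive, so the sampled
    day always leaves strictly positive follow-up). Patients who die on the
    day of diagnosis have an empty window and are excluded.
    """
    end = study_end
    if patient.last_followup_date is not None:
        end = min(end, patient.last_followup_date)
    if patient.death_date is not None:
        end = min(end, patient.death_date)
    n_days = (end - patient.first_hf_date).days
    if n_days <= 0:
        raise PatientExcluded(
            f"patient {patient.patient_id}: no follow-up after HF diagnosis")
    return patient.first_hf_date + timedelta(days=int(rng.integers(0, n_days)))


def build_sequence(patient: PatientRecord, baseline: date, vocab: Vocabulary,
                   max_len: int = 256, include_baseline_day: bool = True) -> TokenSequence:
    """Tokenise history up to baseline into code / age / visit-position channels.

    Encounters sharing a calendar date form one visit and share a visit
    number; ages are integer years computed against July 1 of the birth year.
    The terminal PREDICT token carries the age at baseline and the next visit
    number. Histories longer than ``max_len - 1`` keep the most recent tokens,
    with visit numbers renumbered from 1 over the retained encounters.
    """
    if baseline < patient.registration_start:
        raise ValueError("baseline precedes the patient's record span")
    if include_baseline_day:
        history = [e for e in patient.encounters if e.date <= baseline]
    else:
        history = [e for e in patient.encounters if e.date < baseline]
    history.sort(key=lambda e: e.date)  # stable: same-date order preserved
    if len(history) > max_len - 1:
        history = history[-(max_len - 1):]

    code_ids = np.zeros(max_len, dtype=np.int64)
    age_ids = np.zeros(max_len, dtype=np.int64)
    position_ids = np.zeros(max_len, dtype=np.int64)
    mask = np.zeros(max_len, dtype=np.int64)
    codes: list[str] = [""] * max_len

    visit = 0
    prev_date = None
    for i, enc in enumerate(history):
        if enc.date != prev_date:
            visit += 1
            prev_date = enc.date
        code_ids[i] = vocab.code_id(enc.code)
        age_ids[i] = vocab.age_id(patient.age_years(enc.date))
        position_ids[i] = min(visit, vocab.max_position)
        mask[i] = 1
        codes[i] = enc.code
    k = len(history)
    code_ids[k] = vocab.predict_id
    age_ids[k] = vocab.age_id(patient.age_years(baseline))
    position_ids[k] = min(visit + 1, vocab.max_position)
    mask[k] = 1
    codes[k] = PREDICT
    return TokenSequence(code_ids=code_ids, age_ids=age_ids,
                         position_ids=position_ids, attention_mask=mask,
                         predict_index=k, codes=tuple(codes))


def label_example(patient: PatientRecord, baseline: date,
                  study_end: date) -> SurvivalLabel:
    """Censored survival label in months from baseline.

    Death observed before the earlier of loss to follow-up and study end is an
    event; otherwise the patient is censored at that earlier date.
    """
    censor_date = study_end
    if patient.last_followup_date is not None:
        censor_date = min(censor_date, patient.last_followup_date)
    if patient.death_date is not None and patient.death_date <= censor_date:
        t = (patient.death_date - baseline).days / DAYS_PER_MONTH
        event = 1
    else:
        t = (censor_date - baseline).days / DAYS_PER_MONTH
        event = 0
    if t <= 0:
        raise ValueError("non-positive follow-up time; baseline selection "
                         "should have excluded this patient")
    return SurvivalLabel(time=t, event=event)


def split_by_practice(records: list[PatientRecord], fraction: float = 0.75,
                      rng: np.random.Generator | None = None
                      ) -> tuple[list[PatientRecord], list[PatientRecord]]:
    """Site-level random split: every patient of one site falls on one side."""
    rng = rng or np.random.default_rng(0)
    sites = sorted({r.site for r in records})
    if len(sites) < 2:
        raise ValueError("need at least two sites to split by practice")
    order = list(rng.permutation(len(sites)))
    n_deriv = int(round(fraction * len(sites)))
    n_deriv = min(max(n_deriv, 1), len(sites) - 1)
    deriv_sites = {sites[i] for i in order[:n_deriv]}
    derivation = [r for r in records if r.site in deriv_sites]
    validation = [r for r in records if r.site not in deriv_sites]
    return derivation, validation


# ---------------------------------------------------------------------------
# cohort file I/O (CSV schema shared with the simulator)
# ---------------------------------------------------------------------------

def _parse_date(s: str) -> date | None:
    return date.fromisoformat(s) if s else None


def read_cohort(directory: str | Path) -> list[PatientRecord]:
    """Read patients / encounters / measurements CSVs into PatientRecords."""
    directory = Path(directory)
    patients: dict[str, PatientRecord] = {}
    with open(directory / "patients.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            rec = PatientRecord(
                patient_id=row["patient_id"], sex=row["sex"],
                birth_year=int(row["birth_year"]), site=row["site"],
                registration_start=date.fromisoformat(row["registration_start"]),
                first_hf_date=date.fromisoformat(row["first_hf_date"]),
                hf_subtype=row["hf_subtype"],
                death_date=_parse_date(row["death_date"]),
                last_followup_date=_parse_date(row["last_followup_date"]))
            patients[rec.patient_id] = rec
    with open(directory / "encounters.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            patients[row["patient_id"]].encounters.append(
                Encounter(patient_id=row["patient_id"], code=row["code"],
                          modality=row["modality"],
                          date=date.fromisoformat(row["date"])))
    meas_path = directory / "measurements.csv"
    if meas_path.exists():
        with open(meas_path, newline="") as fh:
            for row in csv.DictReader(fh):
                value = row["value"]
                if row["variable"] not in ("smoking", "NYHA"):
                    value = float(value)
                patients[row["patient_id"]].measurements.append(
                    MeasurementRecord(patient_id=row["patient_id"],
                                      variable=row["variable"], value=value,
                                      date=date.fromisoformat(row["date"])))
    return list(patients.values())
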