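"""Synthetic longitudinal EHR cohorts with known hazard structure.

Every downstream stage — tokenisation, the transformer survival model, the
Cox benchmark, the evaluation metrics, the attribution analysis — is
exercised on cohorts produced here, because the quantities real cohorts hide
(the true linear predictor, the true event time, the censoring time) are
returned alongside the records as a ground-truth oracle.

Generative model
----------------
Patients enter the study at an age drawn uniformly from ``entry_age_range``
(default 40–90 years) on a uniformly drawn calendar day; the entry day doubles
as the first HF diagnosis date. Visits then arrive as a homogeneous Poisson
process in patient time at ``visit_rate`` per year; all codes recorded on one
calendar day form one visit. At each visit a code is first recorded with its
per-visit occurrence probability, and re-recorded at later visits with its
``chronic_rerecord_prob``.

One index date (baseline) is sampled uniformly from the patient's eligibility
window. The true linear predictor at baseline is

    eta_i = sum over distinct codes in history   beta_c * w(dt_c)

with ``w = 1`` for non-decaying effects and ``w = 2^(-dt / half_life)`` for
exponentially decaying ones, ``dt_c`` the months from the code's first
recording to baseline. The event time is exponential with constant rate
``lambda0 * exp(eta_i)`` per month after baseline; dropout censoring is an
independent exponential; administrative censoring occurs at the study end.
The observed record keeps only what a real extract would show: dates, codes,
measurements, and the earlier of death and censoring.

Measurement streams (SBP, BMI, creatinine, sodium, smoking, NYHA) are drawn
around patient-level means at visit dates, with each variable withheld
entirely for a patient at the observed per-variable missingness rates of the
motivating UK heart-failure cohort (e.g. BMI 26.7%, NYHA 96.6%).
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, asdict
from datetime import date, timedelta
from pathlib import Path

import numpy as np

from .corpus import (DAYS_PER_MONTH, Encounter, MeasurementRecord,
                     PatientRecord)

__all__ = ["CodeEffect", "MeasurementModel", "SimulationConfig", "GroundTruth",
           "simulate_cohort", "simulate_measurements", "write_cohort",
           "read_ground_truth", "default_effects", "default_config"]


class ConfigurationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class CodeEffect:
    """Per-code multiplicative hazard effect.

    beta is a log hazard ratio; decay="exponential" halves the contribution
    every ``half_life_months`` between first recording and baseline.
    """
    code: str
    modality: str = "diagnosis"
    beta: float = 0.0
    decay: str = "none"                 # "none" | "exponential"
    half_life_months: float | None = None
    chronic_rerecord_prob: float = 0.0
    prevalence: float | None = None     # per-visit; None -> config default

    def __post_init__(self):
        if self.decay not in ("none", "exponential"):
            raise ConfigurationError(f"unknown decay {self.decay!r}")
        if self.decay == "exponential" and not (self.half_life_months and
                                                self.half_life_months > 0):
            raise ConfigurationError("exponential decay requires half_life_months > 0")
        if not 0.0 <= self.chronic_rerecord_prob <= 1.0:
            raise ConfigurationError("chronic_rerecord_prob must lie in [0,1]")

    def weight(self, months_before_baseline: float) -> float:
        if self.decay == "none":
            return 1.0
        return 2.0 ** (-months_before_baseline / self.half_life_months)


@dataclass
class MeasurementModel:
    """Distribution of one measurement stream plus its missingness."""
    mean: float | None = None        # numeric variables
    sd: float | None = None
    within_sd: float | None = None   # visit-to-visit noise; default 0.3*sd
    levels: tuple | None = None      # categorical variables
    level_probs: tuple | None = None
    missingness: float = 0.0         # probability the variable is withheld

    def __post_init__(self):
        if not 0.0 <= self.missingness <= 1.0:
            raise ConfigurationError("missingness must lie in [0,1]")


def default_measurement_models() -> dict[str, MeasurementModel]:
    """Measurement distributions matching the motivating cohort's medians and
    its reported per-variable missingness fractions."""
    return {
        "SBP": MeasurementModel(mean=134.0, sd=14.0, missingness=0.040),
        "BMI": MeasurementModel(mean=27.5, sd=5.5, missingness=0.267),
        "creatinine": MeasurementModel(mean=91.3, sd=28.0, missingness=0.091),
        "sodium": MeasurementModel(mean=139.6, sd=2.8, missingness=0.097),
        "smoking": MeasurementModel(levels=("no", "ex", "yes"),
                                    level_probs=(0.438, 0.433, 0.129),
                                    missingness=0.140),
        "NYHA": MeasurementModel(levels=("I", "II", "III", "IV"),
                                 level_probs=(0.25, 0.47, 0.25, 0.03),
                                 missingness=0.966),
    }


@dataclass
class SimulationConfig:
    n_patients: int = 2000
    study_start: date = date(2010, 1, 1)
    study_end: date = date(2019, 12, 31)
    entry_age_range: tuple[float, float] = (40.0, 90.0)
    visit_rate: float = 6.0            # visits per patient-year
    code_prevalence: float = 0.03      # first-recording probability per visit
    effects: list[CodeEffect] = field(default_factory=list)
    baseline_hazard_lambda0: float = 0.02   # events per month
    dropout_rate: float = 0.01              # censorings per month
    measurement_models: dict[str, MeasurementModel] = field(
        default_factory=default_measurement_models)
    female_fraction: float = 0.46
    n_sites: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.n_patients <= 0:
            raise ConfigurationError("n_patients must be positive")
        if self.baseline_hazard_lambda0 <= 0:
            raise ConfigurationError("baseline_hazard_lambda0 must be positive")
        if self.study_start >= self.study_end:
            raise ConfigurationError("study_start must precede study_end")
        if not 0.0 <= self.code_prevalence <= 1.0:
            raise ConfigurationError("code_prevalence must lie in [0,1]")
        if self.visit_rate < 0 or self.dropout_rate < 0:
            raise ConfigurationError("rates must be non-negative")

    def to_json(self) -> dict:
        d = asdict(self)
        d["study_start"] = self.study_start.isoformat()
        d["study_end"] = self.study_end.isoformat()
        return d


@dataclass
class GroundTruth:
    patient_id: str
    eta: float               # true linear predictor at baseline
    true_event_time: float   # months from baseline (latent, uncensored)
    censor_time: float       # months from baseline (dropout ∧ administrative)
    index_date: date         # the sampled baseline


def default_effects(n_codes: int = 30, n_causal: int = 5,
                    beta_range: tuple[float, float] = (0.5, 1.5),
                    decay_half_life: float | None = None,
                    seed: int = 0) -> list[CodeEffect]:
    """A study vocabulary: ``n_causal`` codes with |beta| in ``beta_range``
    (alternating sign), the rest null. Codes cycle through the three
    modalities with ICD-10 / BNF-section / OPCS-shaped names."""
    rng = np.random.default_rng(seed)
    effects = []
    for i in range(n_codes):
        modality = ("diagnosis", "medication", "procedure")[i % 3]
        code = {"diagnosis": f"D{i:02d}.{i % 10}",
                "medication": f"{i:02d}05",
                "procedure": f"P{i:02d}"}[modality]
        if i < n_causal:
            beta = float(rng.uniform(*beta_range)) * (1 if i % 2 == 0 else -1)
        else:
            beta = 0.0
        kwargs = {}
        if decay_half_life is not None and i < n_causal:
            kwargs = {"decay": "exponential", "half_life_months": decay_half_life}
        effects.append(CodeEffect(code=code, modality=modality, beta=beta, **kwargs))
    return effects


def default_config(n_patients: int = 2000, seed: int = 0, **overrides
                   ) -> SimulationConfig:
    effects = overrides.pop("effects", None)
    if effects is None:
        effects = default_effects(seed=seed)
    return SimulationConfig(n_patients=n_patients, effects=effects, seed=seed,
                            **overrides)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _simulate_patient(pid: str, config: SimulationConfig,
                      rng: np.random.Generator
                      ) -> tuple[PatientRecord, GroundTruth, list[date]]:
    sex = "female" if rng.random() < config.female_fraction else "male"
    study_days = (config.study_end - config.study_start).days
    # entry (= first HF diagnosis) uniform, leaving at least one day of window
    entry = config.study_start + timedelta(days=int(rng.integers(0, study_days)))
    entry_age = rng.uniform(*config.entry_age_range)
    birth_year = entry.year - int(math.floor(entry_age))
    site = f"site{int(rng.integers(0, config.n_sites)):02d}"

    # visit stream: homogeneous Poisson in patient time from entry to study end
    visit_dates: list[date] = [entry]
    if config.visit_rate > 0:
        t_days = 0.0
        mean_gap = 365.25 / config.visit_rate
        horizon_days = (config.study_end - entry).days
        while True:
            t_days += rng.exponential(mean_gap)
            if t_days >= horizon_days:
                break
            d = entry + timedelta(days=int(math.ceil(t_days)))
            if d != visit_dates[-1]:
                visit_dates.append(d)

    # code recording per visit
    encounters: list[Encounter] = []
    first_recorded: dict[str, date] = {}
    for vd in visit_dates:
        for eff in config.effects:
            prev = eff.prevalence if eff.prevalence is not None else config.code_prevalence
            if eff.code not in first_recorded:
                if rng.random() < prev:
                    first_recorded[eff.code] = vd
                    encounters.append(Encounter(pid, eff.code, eff.modality, vd))
            elif rng.random() < eff.chronic_rerecord_prob:
                encounters.append(Encounter(pid, eff.code, eff.modality, vd))

    # baseline uniform over [entry, study_end)
    window_days = (config.study_end - entry).days
    baseline = entry + timedelta(days=int(rng.integers(0, max(window_days, 1))))

    # true linear predictor at baseline from distinct codes in history
    eta = 0.0
    for eff in config.effects:
        first = first_recorded.get(eff.code)
        if first is not None and first <= baseline:
            dt = (baseline - first).days / DAYS_PER_MONTH
            eta += eff.beta * eff.weight(dt)

    rate = config.baseline_hazard_lambda0 * math.exp(eta)
    true_event_time = rng.exponential(1.0 / rate)
    dropout_time = (rng.exponential(1.0 / config.dropout_rate)
                    if config.dropout_rate > 0 else math.inf)
    admin_time = (config.study_end - baseline).days / DAYS_PER_MONTH
    censor_time = min(dropout_time, admin_time)

    death_date = None
    last_followup = config.study_end
    if true_event_time < censor_time:
        death_days = max(1, int(round(true_event_time * DAYS_PER_MONTH)))
        death_date = baseline + timedelta(days=death_days)
        end_date = death_date
    elif dropout_time < admin_time:
        last_followup = baseline + timedelta(
            days=max(1, int(round(dropout_time * DAYS_PER_MONTH))))
        end_date = last_followup
    else:
        end_date = config.study_end

    encounters = [e for e in encounters if e.date <= end_date]
    record = PatientRecord(patient_id=pid, sex=sex, birth_year=birth_year,
                           site=site, registration_start=entry,
                           first_hf_date=entry, death_date=death_date,
                           last_followup_date=last_followup,
                           encounters=sorted(encounters, key=lambda e: e.date))
    truth = GroundTruth(patient_id=pid, eta=eta, true_event_time=true_event_time,
                        censor_time=censor_time, index_date=baseline)
    return record, truth, [d for d in visit_dates if d <= end_date]


def simulate_measurements(patient: PatientRecord, config: SimulationConfig,
                          rng: np.random.Generator,
                          visit_dates: list[date] | None = None
                          ) -> list[MeasurementRecord]:
    """Draw measurement streams at the patient's visit dates.

    Numeric variables fluctuate around a patient-level mean; categorical ones
    carry a fixed patient-level status. Each variable is withheld entirely
    with its configured missingness probability. Without an explicit visit
    stream the distinct encounter dates are used.
    """
    if visit_dates is None:
        visit_dates = sorted({e.date for e in patient.encounters})
    out: list[MeasurementRecord] = []
    for var, model in config.measurement_models.items():
        if model.levels is None and model.mean is None:
            raise ConfigurationError(f"measurement model for {var!r} needs "
                                     "either mean/sd or levels")
        if rng.random() < model.missingness:
            continue
        if not visit_dates:
            continue
        if model.levels is not None:
            status = model.levels[rng.choice(len(model.levels), p=model.level_probs)]
            for vd in visit_dates:
                out.append(MeasurementRecord(patient.patient_id, var, status, vd))
        else:
            centre = rng.normal(model.mean, model.sd)
            wsd = model.within_sd if model.within_sd is not None else 0.3 * model.sd
            for vd in visit_dates:
                out.append(MeasurementRecord(patient.patient_id, var,
                                             float(rng.normal(centre, wsd)), vd))
    return out


def simulate_cohort(config: SimulationConfig
                    ) -> tuple[list[PatientRecord], list[GroundTruth]]:
    """Simulate a full cohort; deterministic given ``config.seed``."""
    ss = np.random.SeedSequence(config.seed)
    child_seeds = ss.spawn(config.n_patients)
    records, truths = [], []
    for i in range(config.n_patients):
        rng = np.random.default_rng(child_seeds[i])
        rec, truth, visits = _simulate_patient(f"p{i:06d}", config, rng)
        rec.measurements = simulate_measurements(rec, config, rng, visits)
        records.append(rec)
        truths.append(truth)
    return records, truths


# ---------------------------------------------------------------------------
# file output (schema shared with corpus.read_cohort)
# ---------------------------------------------------------------------------

def write_cohort(records: list[PatientRecord], ground_truth: list[GroundTruth],
                 directory: str | Path, config: SimulationConfig | None = None
                 ) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "patients.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "sex", "birth_year", "site",
                    "registration_start", "first_hf_date", "hf_subtype",
                    "death_date", "last_followup_date"])
        for r in records:
            w.writerow([r.patient_id, r.sex, r.birth_year, r.site,
                        r.registration_start.isoformat(),
                        r.first_hf_date.isoformat(), r.hf_subtype,
                        r.death_date.isoformat() if r.death_date else "",
                        r.last_followup_date.isoformat() if r.last_followup_date else ""])
    with open(directory / "encounters.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "date", "modality", "code"])
        for r in records:
            for e in r.encounters:
                w.writerow([e.patient_id, e.date.isoformat(), e.modality, e.code])
    with open(directory / "measurements.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "date", "variable", "value"])
        for r in records:
            for m in r.measurements:
                value = m.value if isinstance(m.value, str) else repr(m.value)
                w.writerow([m.patient_id, m.date.isoformat(), m.variable, value])
    with open(directory / "ground_truth.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "eta", "true_event_time", "censor_time",
                    "index_date"])
        for g in ground_truth:
            w.writerow([g.patient_id, repr(g.eta), repr(g.true_event_time),
                        repr(g.censor_time), g.index_date.isoformat()])
    if config is not None:
        with open(directory / "config.json", "w") as fh:
            json.dump(config.to_json(), fh, indent=2, default=str)


def read_ground_truth(directory: str | Path) -> list[GroundTruth]:
    with open(Path(directory) / "ground_truth.csv", newline="") as fh:
        return [GroundTruth(patient_id=row["patient_id"], eta=float(row["eta"]),
                            true_event_time=float(row["true_event_time"]),
                            censor_time=float(row["censor_time"]),
                            index_date=date.fromisoformat(row["index_date"]))
                for row in csv.DictReader(fh)]
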