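"""Cox proportional-hazards benchmark with multiple imputation.

An EHR adaptation of the MAGGIC heart-failure risk model: baseline
covariates are extracted from the record (windowed averages of vitals and
labs, last known smoking status, ever-before-baseline disease and procedure
flags, HF subtype in place of LVEF), missing values are multiply imputed by
chained equations with the Nelson–Aalen cumulative-hazard estimate as an
auxiliary variable, one Cox model is fitted per completed dataset, the
coefficient sets are pooled with Rubin's rules, and survival predictions are
pooled on the complementary log-log scale.

Two covariate sets are provided: ``standard`` (sex, age, smoking, diabetes,
SBP, creatinine, BMI, NYHA class, COPD, beta-blockers, ACE-I/ARBs, HF
duration >= 18 months, HF subtype, plus age x subtype and SBP x subtype
interactions) and ``extended`` which adds sodium, atrial fibrillation,
stroke, myocardial infarction, PCI and CABG.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd

from .corpus import DAYS_PER_MONTH, PatientRecord

logger = logging.getLogger(__name__)

__all__ = ["CovariateRow", "CoxFit", "PooledModel", "extract_covariates",
           "covariate_frame", "nelson_aalen", "impute_chained", "fit_cox",
           "pool_rubin", "pool_predictions", "run_benchmark"]

CONTINUOUS_WINDOWED = ("SBP", "creatinine", "BMI", "sodium")
STANDARD_IMPUTED = ("SBP", "smoking", "BMI", "creatinine", "NYHA")
EXTENDED_IMPUTED = STANDARD_IMPUTED + ("sodium",)

#: covariate name -> diagnosis/medication/procedure codes that set the flag
DEFAULT_CODE_GROUPS: dict[str, set] = {
    "diabetes": set(), "COPD": set(), "beta_blocker": set(),
    "acei_arb": set(), "AF": set(), "stroke": set(), "MI": set(),
    "PCI": set(), "CABG": set()}

FLAGS_STANDARD = ("diabetes", "COPD", "beta_blocker", "acei_arb")
FLAGS_EXTENDED = ("AF", "stroke", "MI", "PCI", "CABG")


@dataclass
class CovariateRow:
    patient_id: str
    sex: str
    age: float
    smoking: str | None
    diabetes: int
    SBP: float | None
    creatinine: float | None
    BMI: float | None
    NYHA: str | None
    COPD: int
    beta_blocker: int
    acei_arb: int
    hf_ge_18_months: int
    hf_subtype: str
    sodium: float | None = None
    AF: int = 0
    stroke: int = 0
    MI: int = 0
    PCI: int = 0
    CABG: int = 0


def extract_covariates(patient: PatientRecord, baseline: date,
                       variant: str = "standard",
                       code_groups: dict[str, set] | None = None
                       ) -> CovariateRow:
    """Baseline covariates from the raw record.

    Continuous measurements are averaged over the 36 months up to baseline;
    smoking and NYHA class use the last known value in that window; disease
    and procedure flags are set by any matching code ever before baseline.
    Absent values stay None (a missingness marker, not an error).
    """
    if variant not in ("standard", "extended"):
        raise ValueError(f"unknown variant {variant!r}")
    groups = {**DEFAULT_CODE_GROUPS, **(code_groups or {})}
    window_start_days = 36 * DAYS_PER_MONTH

    def in_window(d: date) -> bool:
        back = (baseline - d).days
        return 0 <= back < window_start_days

    values: dict[str, list] = {v: [] for v in CONTINUOUS_WINDOWED}
    last_cat: dict[str, tuple[date, str]] = {}
    for m in patient.measurements:
        if m.date > baseline:
            continue
        if m.variable in values and in_window(m.date):
            values[m.variable].append(float(m.value))
        elif m.variable in ("smoking", "NYHA") and in_window(m.date):
            prev = last_cat.get(m.variable)
            if prev is None or m.date >= prev[0]:
                last_cat[m.variable] = (m.date, str(m.value))

    flags = {name: 0 for name in groups}
    for enc in patient.encounters:
        if enc.date > baseline:
            continue
        for name, codes in groups.items():
            if enc.code in codes:
                flags[name] = 1

    months_since_hf = (baseline - patient.first_hf_date).days / DAYS_PER_MONTH
    mean = {v: (float(np.mean(values[v])) if values[v] else None)
            for v in CONTINUOUS_WINDOWED}
    return CovariateRow(
        patient_id=patient.patient_id, sex=patient.sex,
        age=patient.age_years(baseline),
        smoking=last_cat.get("smoking", (None, None))[1],
        diabetes=flags["diabetes"], SBP=mean["SBP"],
        creatinine=mean["creatinine"], BMI=mean["BMI"],
        NYHA=last_cat.get("NYHA", (None, None))[1],
        COPD=flags["COPD"], beta_blocker=flags["beta_blocker"],
        acei_arb=flags["acei_arb"],
        hf_ge_18_months=int(months_since_hf >= 18.0),
        hf_subtype=patient.hf_subtype,
        sodium=mean["sodium"] if variant == "extended" else None,
        AF=flags["AF"], stroke=flags["stroke"], MI=flags["MI"],
        PCI=flags["PCI"], CABG=flags["CABG"])


def covariate_frame(rows: list[CovariateRow]) -> pd.DataFrame:
    df = pd.DataFrame([r.__dict__ for r in rows]).set_index("patient_id")
    return df


# ---------------------------------------------------------------------------
# Nelson–Aalen auxiliary
# ---------------------------------------------------------------------------

def nelson_aalen(times, events) -> "NelsonAalen":
    """Nelson–Aalen cumulative-hazard step function H(t) = Σ_{t_i≤t} d_i/n_i."""
    times = np.asarray(times, float)
    events = np.asarray(events).astype(int)
    if times.size == 0:
        raise ValueError("empty input")
    if (times <= 0).any():
        raise ValueError("times must be positive")
    order = np.argsort(times, kind="stable")
    t_sorted, e_sorted = times[order], events[order]
    uniq, start = np.unique(t_sorted, return_index=True)
    n_at_risk = len(times) - start
    d = np.add.reduceat(e_sorted, start)
    increments = d / n_at_risk
    return NelsonAalen(uniq, np.cumsum(increments))


@dataclass
class NelsonAalen:
    event_times: np.ndarray
    cumhaz: np.ndarray

    def __call__(self, t) -> np.ndarray:
        idx = np.searchsorted(self.event_times, np.asarray(t, float),
                              side="right") - 1
        out = np.where(idx >= 0, self.cumhaz[np.clip(idx, 0, None)], 0.0)
        return out


# ---------------------------------------------------------------------------
# chained-equation imputation
# ---------------------------------------------------------------------------

_CATEGORICAL = {"smoking": ("no", "ex", "yes"), "NYHA": ("I", "II", "III", "IV")}


def _design_for_imputation(df: pd.DataFrame, target: str,
                           numeric_cols: list[str]) -> np.ndarray:
    """Predictor matrix: all other model variables, categoricals as dummies."""
    cols = []
    for c in numeric_cols:
        if c != target:
            cols.append(df[c].to_numpy(float))
    for c, levels in _CATEGORICAL.items():
        if c == target or c not in df.columns:
            continue
        for lv in levels[1:]:
            cols.append((df[c] == lv).to_numpy(float))
    return np.column_stack(cols)


def impute_chained(df: pd.DataFrame, times, events, m: int = 5,
                   n_sweeps: int = 10, rng: np.random.Generator | None = None,
                   variant: str = "standard") -> list[pd.DataFrame]:
    """Multiple imputation by chained equations.

    Continuous variables are imputed by predictive mean matching (5 donors,
    coefficients perturbed by a normal draw around the least-squares fit);
    categorical variables by multinomial logistic regression sampling. The
    event indicator and the Nelson–Aalen cumulative-hazard estimate at each
    patient's observed time enter every imputation model as auxiliary
    predictors. Returns ``m`` independently completed copies.
    """
    rng = rng or np.random.default_rng(0)
    to_impute = list(EXTENDED_IMPUTED if variant == "extended" else STANDARD_IMPUTED)
    to_impute = [v for v in to_impute if v in df.columns]
    na = nelson_aalen(times, events)
    aux = pd.DataFrame({"_event": np.asarray(events, float),
                        "_cumhaz": na(np.asarray(times, float))}, index=df.index)
    work_base = pd.concat([df.copy(), aux], axis=1)

    missing = {v: work_base[v].isna().to_numpy() for v in to_impute}
    for v in to_impute:
        if missing[v].all():
            raise ValueError(f"variable {v!r} is 100% missing; exclude it "
                             "from the model instead of imputing")
    if not any(mk.any() for mk in missing.values()):
        return [df.copy() for _ in range(m)]

    numeric_targets = [v for v in to_impute if v not in _CATEGORICAL]
    numeric_cols = [c for c in work_base.columns
                    if c not in _CATEGORICAL
                    and c not in ("sex", "hf_subtype")
                    and pd.api.types.is_numeric_dtype(work_base[c])]

    out = []
    for rep in range(m):
        rrng = np.random.default_rng(rng.integers(0, 2**31))
        work = work_base.copy()
        # initial fill: random draws from the observed values
        for v in to_impute:
            obs = work.loc[~missing[v], v].to_numpy()
            work.loc[missing[v], v] = rrng.choice(obs, size=missing[v].sum())
        if work[numeric_cols].isna().any().any():
            raise ValueError("unexpected missingness outside imputed variables")
        for _ in range(n_sweeps):
            for v in to_impute:
                mask = missing[v]
                if not mask.any():
                    continue
                X = _design_for_imputation(work, v, numeric_cols)
                X = np.column_stack([np.ones(len(X)), X])
                if v in _CATEGORICAL:
                    _impute_categorical(work, v, X, mask, rrng)
                else:
                    _impute_pmm(work, v, X, mask, rrng)
        completed = work[df.columns].copy()
        for v in numeric_targets:
            completed[v] = completed[v].astype(float)
        out.append(completed)
    return out


def _impute_pmm(work: pd.DataFrame, v: str, X: np.ndarray, mask: np.ndarray,
                rng: np.random.Generator, n_donors: int = 5) -> None:
    y = work[v].to_numpy(float)
    Xo, yo = X[~mask], y[~mask]
    beta, *_ = np.linalg.lstsq(Xo, yo, rcond=None)
    resid = yo - Xo @ beta
    dof = max(len(yo) - X.shape[1], 1)
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.pinv(Xo.T @ Xo)
    # eigh handles the rank-deficient case (collinear or constant predictors)
    cov += 1e-10 * np.eye(len(cov))
    beta_star = rng.multivariate_normal(beta, cov, method="eigh")
    pred_obs = Xo @ beta
    pred_mis = X[mask] @ beta_star
    # 5 nearest observed donors by predicted value; draw one at random
    order = np.argsort(pred_obs, kind="stable")
    sorted_pred = pred_obs[order]
    imputed = np.empty(mask.sum())
    for i, pm in enumerate(pred_mis):
        pos = np.searchsorted(sorted_pred, pm)
        lo = max(0, pos - n_donors)
        hi = min(len(sorted_pred), pos + n_donors)
        window = order[lo:hi]
        dist = np.abs(pred_obs[window] - pm)
        donors = window[np.argsort(dist, kind="stable")[:n_donors]]
        imputed[i] = yo[donors[rng.integers(0, len(donors))]]
    vals = work[v].to_numpy(float)
    vals[mask] = imputed
    work[v] = vals


def _impute_categorical(work: pd.DataFrame, v: str, X: np.ndarray,
                        mask: np.ndarray, rng: np.random.Generator) -> None:
    from sklearn.linear_model import LogisticRegression
    levels = _CATEGORICAL[v]
    y = work[v].to_numpy(object)
    present = sorted(set(y[~mask]), key=levels.index)
    if len(present) < 2:
        work.loc[mask, v] = present[0]
        return
    clf = LogisticRegression(max_iter=200, C=1.0)
    clf.fit(X[~mask], y[~mask])
    probs = clf.predict_proba(X[mask])
    draws = [clf.classes_[rng.choice(len(clf.classes_), p=p / p.sum())]
             for p in probs]
    work.loc[mask, v] = draws


# ---------------------------------------------------------------------------
# Cox fitting and pooling
# ---------------------------------------------------------------------------

@dataclass
class CoxFit:
    terms: list
    coefficients: np.ndarray
    covariance: np.ndarray
    fitter: object = None        # lifelines CoxPHFitter, for predictions
    dropped_terms: list = field(default_factory=list)


def _design_matrix(df: pd.DataFrame, variant: str) -> pd.DataFrame:
    X = pd.DataFrame(index=df.index)
    X["male"] = (df["sex"] == "male").astype(float)
    X["age"] = df["age"].astype(float)
    X["smoking_ex"] = (df["smoking"] == "ex").astype(float)
    X["smoking_yes"] = (df["smoking"] == "yes").astype(float)
    for c in ("diabetes", "SBP", "creatinine", "BMI", "COPD",
              "beta_blocker", "acei_arb", "hf_ge_18_months"):
        X[c] = df[c].astype(float)
    for lv in ("II", "III", "IV"):
        X[f"NYHA_{lv}"] = (df["NYHA"] == lv).astype(float)
    for lv in ("reduced", "preserved"):
        X[f"subtype_{lv}"] = (df["hf_subtype"] == lv).astype(float)
        X[f"age_x_{lv}"] = X["age"] * X[f"subtype_{lv}"]
        X[f"SBP_x_{lv}"] = X["SBP"] * X[f"subtype_{lv}"]
    if variant == "extended":
        for c in ("sodium", "AF", "stroke", "MI", "PCI", "CABG"):
            X[c] = df[c].astype(float)
    return X


def fit_cox(df: pd.DataFrame, times, events,
            variant: str = "standard") -> CoxFit:
    """Cox partial-likelihood fit (Breslow baseline) on a completed dataset.

    Zero-variance design columns (e.g. an HF subtype absent from the cohort)
    are dropped and recorded in ``dropped_terms``.
    """
    from lifelines import CoxPHFitter
    X = _design_matrix(df, variant)
    if X.isna().any().any():
        raise ValueError("design matrix contains missing values; impute first")
    variances = X.var(axis=0)
    dropped = [c for c in X.columns if variances[c] < 1e-12]
    X = X.drop(columns=dropped)
    data = X.copy()
    data["time"] = np.asarray(times, float)
    data["event"] = np.asarray(events).astype(int)
    if data["event"].sum() == 0:
        raise ValueError("no events; cannot fit a Cox model")
    cph = CoxPHFitter(penalizer=1e-6, baseline_estimation_method="breslow")
    cph.fit(data, duration_col="time", event_col="event")
    return CoxFit(terms=list(X.columns),
                  coefficients=cph.params_.to_numpy(),
                  covariance=cph.variance_matrix_.to_numpy(),
                  fitter=cph, dropped_terms=dropped)


@dataclass
class PooledModel:
    m: int
    terms: list
    coefficients: np.ndarray          # pooled point estimates
    within_variance: np.ndarray       # W, componentwise
    between_variance: np.ndarray      # B, componentwise
    total_variance: np.ndarray        # W + (1 + 1/m) B
    fits: list = field(default_factory=list)


def pool_rubin(fits: list[CoxFit]) -> PooledModel:
    """Rubin's rules over per-imputation Cox fits."""
    if len(fits) < 2:
        raise ValueError("need at least two fits to pool")
    terms = fits[0].terms
    for f in fits[1:]:
        if f.terms != terms:
            raise ValueError("imputation fits have mismatched terms")
    est = np.stack([f.coefficients for f in fits])
    m = len(fits)
    pooled = est.mean(axis=0)
    W = np.stack([np.diag(f.covariance) for f in fits]).mean(axis=0)
    B = est.var(axis=0, ddof=1)
    total = W + (1.0 + 1.0 / m) * B
    return PooledModel(m=m, terms=terms, coefficients=pooled,
                       within_variance=W, between_variance=B,
                       total_variance=total, fits=fits)


def pool_predictions(per_imputation_S: np.ndarray,
                     eps: float = 1e-12) -> np.ndarray:
    """Pool survival probabilities across imputations on the cloglog scale.

    pooled S = exp(−exp(mean_m log(−log S_m))). Inputs exactly 0 or 1 are
    an error; callers clip into (eps, 1−eps) explicitly.
    """
    S = np.asarray(per_imputation_S, float)
    if ((S <= 0) | (S >= 1)).any():
        raise ValueError("survival probabilities must lie strictly in (0,1); "
                         "clip before pooling")
    cloglog = np.log(-np.log(S))
    return np.exp(-np.exp(cloglog.mean(axis=0)))


# ---------------------------------------------------------------------------
# end-to-end benchmark
# ---------------------------------------------------------------------------

def run_benchmark(deriv_df: pd.DataFrame, deriv_times, deriv_events,
                  valid_df: pd.DataFrame, valid_times, valid_events,
                  tau: float, variant: str = "standard", m: int = 5,
                  seed: int = 0) -> tuple[PooledModel, np.ndarray]:
    """Impute derivation and validation separately, fit m Cox models, pool.

    Returns the pooled model and the cloglog-pooled risk 1 − S(tau) for each
    validation patient (imputation i of the validation set scored by the
    model fitted on imputation i of the derivation set).
    """
    rng = np.random.default_rng(seed)
    deriv_sets = impute_chained(deriv_df, deriv_times, deriv_events, m=m,
                                rng=rng, variant=variant)
    valid_sets = impute_chained(valid_df, valid_times, valid_events, m=m,
                                rng=rng, variant=variant)
    fits = [fit_cox(d, deriv_times, deriv_events, variant) for d in deriv_sets]
    pooled = pool_rubin(fits)
    S = np.empty((m, len(valid_df)))
    for i, (fit, vset) in enumerate(zip(fits, valid_sets)):
        Xv = _design_matrix(vset, variant)[fit.terms]
        surv = fit.fitter.predict_survival_function(Xv, times=[tau])
        S[i] = surv.iloc[0].to_numpy()
    S = np.clip(S, 1e-12, 1 - 1e-12)
    return pooled, 1.0 - pool_predictions(S)
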