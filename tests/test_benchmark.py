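"""Covariate extraction, imputation, Cox fitting and Rubin pooling."""

from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest

from seqsurv import benchmark as bm
from seqsurv.corpus import (DAYS_PER_MONTH, Encounter, MeasurementRecord,
                            PatientRecord)


def make_patient(pid="p1", measurements=(), encounters=(),
                 first_hf=date(2014, 1, 1)):
    return PatientRecord(
        patient_id=pid, sex="male", birth_year=1945, site="s1",
        registration_start=date(2010, 1, 1), first_hf_date=first_hf,
        last_followup_date=date(2019, 12, 31),
        encounters=list(encounters), measurements=list(measurements))


# ---------------------------------------------------------------------------
# covariate extraction
# ---------------------------------------------------------------------------

def test_windowed_mean_excludes_old_records():
    base = date(2018, 1, 1)
    dates_back = [40, 10, 2]  # months before baseline
    values = [130.0, 140.0, 150.0]
    meas = [MeasurementRecord("p1", "SBP", v,
                              base - timedelta(days=int(mb * DAYS_PER_MONTH)))
            for mb, v in zip(dates_back, values)]
    row = bm.extract_covariates(make_patient(measurements=meas), base)
    assert row.SBP == pytest.approx(145.0)  # the 40-months-old record excluded


def test_missing_measurement_stays_none():
    row = bm.extract_covariates(make_patient(), date(2018, 1, 1))
    assert row.BMI is None and row.smoking is None and row.NYHA is None


def test_disease_flags_use_ever_history():
    base = date(2018, 1, 1)
    old_mi = Encounter("p1", "I21.9", "diagnosis", date(2010, 3, 1))  # 8 years
    row = bm.extract_covariates(
        make_patient(encounters=[old_mi]), base, variant="extended",
        code_groups={"MI": {"I21.9"}})
    assert row.MI == 1


def test_smoking_last_known_in_window():
    base = date(2018, 1, 1)
    meas = [MeasurementRecord("p1", "smoking", "yes", date(2016, 1, 1)),
            MeasurementRecord("p1", "smoking", "ex", date(2017, 6, 1))]
    row = bm.extract_covariates(make_patient(measurements=meas), base)
    assert row.smoking == "ex"


def test_hf_duration_flag():
    base = date(2018, 1, 1)
    row = bm.extract_covariates(make_patient(first_hf=date(2014, 1, 1)), base)
    assert row.hf_ge_18_months == 1
    row2 = bm.extract_covariates(make_patient(first_hf=date(2017, 6, 1)), base)
    assert row2.hf_ge_18_months == 0


# ---------------------------------------------------------------------------
# Nelson–Aalen
# ---------------------------------------------------------------------------

def test_nelson_aalen_hand_fixture():
    na = bm.nelson_aalen([1.0, 2.0, 3.0], [1, 1, 1])
    assert na(1.0) == pytest.approx(1 / 3, abs=1e-4)
    assert na(2.0) == pytest.approx(1 / 3 + 1 / 2, abs=1e-4)
    assert na(3.0) == pytest.approx(1 / 3 + 1 / 2 + 1.0, abs=1e-4)
    assert na(0.5) == 0.0


def test_nelson_aalen_all_censored_is_zero_and_monotone():
    na = bm.nelson_aalen([1.0, 5.0, 9.0], [0, 0, 0])
    assert np.all(na(np.linspace(0, 10, 50)) == 0.0)
    rng = np.random.default_rng(0)
    t = rng.exponential(10, 200)
    e = rng.integers(0, 2, 200)
    vals = bm.nelson_aalen(t, e)(np.sort(t))
    assert np.all(np.diff(vals) >= 0)


def test_nelson_aalen_matches_lifelines():
    from lifelines import NelsonAalenFitter
    rng = np.random.default_rng(1)
    t = rng.exponential(10, 300).round(2) + 0.01
    e = rng.integers(0, 2, 300)
    ours = bm.nelson_aalen(t, e)
    naf = NelsonAalenFitter(nelson_aalen_smoothing=False)
    naf.fit(t, e)
    grid = np.quantile(t, [0.2, 0.5, 0.8])
    theirs = naf.cumulative_hazard_at_times(grid).to_numpy()
    assert np.allclose(ours(grid), theirs, atol=1e-10)


def test_nelson_aalen_empty_errors():
    with pytest.raises(ValueError):
        bm.nelson_aalen([], [])


# ---------------------------------------------------------------------------
# chained-equation imputation
# ---------------------------------------------------------------------------

def complete_frame(n, rng):
    df = pd.DataFrame({
        "sex": rng.choice(["male", "female"], n),
        "age": rng.uniform(50, 90, n),
        "smoking": rng.choice(["no", "ex", "yes"], n, p=[0.5, 0.35, 0.15]),
        "diabetes": rng.integers(0, 2, n),
        "SBP": rng.normal(134, 14, n),
        "creatinine": rng.normal(91, 20, n),
        "BMI": rng.normal(27.5, 5, n),
        "NYHA": rng.choice(["I", "II", "III", "IV"], n, p=[0.25, 0.45, 0.25, 0.05]),
        "COPD": rng.integers(0, 2, n),
        "beta_blocker": rng.integers(0, 2, n),
        "acei_arb": rng.integers(0, 2, n),
        "hf_ge_18_months": rng.integers(0, 2, n),
        "hf_subtype": rng.choice(["unknown", "reduced", "preserved"], n),
    }, index=[f"p{i}" for i in range(n)])
    return df


def test_no_missing_returns_identical_copies():
    rng = np.random.default_rng(2)
    df = complete_frame(80, rng)
    times = rng.exponential(20, 80) + 0.1
    events = rng.integers(0, 2, 80)
    out = bm.impute_chained(df, times, events, m=3, rng=rng)
    assert len(out) == 3
    for c in out:
        pd.testing.assert_frame_equal(c, df)


def test_pmm_values_come_from_observed_support():
    rng = np.random.default_rng(3)
    df = complete_frame(150, rng)
    times = rng.exponential(20, 150) + 0.1
    events = rng.integers(0, 2, 150)
    mask = rng.uniform(size=150) < 0.3
    observed = set(df.loc[~mask, "SBP"])
    df.loc[mask, "SBP"] = np.nan
    out = bm.impute_chained(df, times, events, m=2, rng=rng)
    for c in out:
        assert set(c.loc[mask, "SBP"]) <= observed


def test_mcar_recovery_of_mean():
    rng = np.random.default_rng(4)
    n = 400
    df = complete_frame(n, rng)
    times = rng.exponential(20, n) + 0.1
    events = rng.integers(0, 2, n)
    full_mean = df["SBP"].mean()
    se = df["SBP"].std() / np.sqrt(n)
    mask = rng.uniform(size=n) < 0.3
    df.loc[mask, "SBP"] = np.nan
    out = bm.impute_chained(df, times, events, m=5, rng=rng)
    pooled_mean = np.mean([c["SBP"].mean() for c in out])
    assert abs(pooled_mean - full_mean) < 2 * se


def test_fully_missing_variable_errors():
    rng = np.random.default_rng(5)
    df = complete_frame(50, rng)
    df["BMI"] = np.nan
    with pytest.raises(ValueError, match="100% missing"):
        bm.impute_chained(df, np.ones(50), np.ones(50, int), m=2, rng=rng)


# ---------------------------------------------------------------------------
# Cox fitting
# ---------------------------------------------------------------------------

def cox_sim(n, beta, rng):
    df = complete_frame(n, rng)
    x = df["diabetes"].to_numpy(float)
    rate = 0.03 * np.exp(beta * x)
    t_event = rng.exponential(1 / rate)
    censor = rng.uniform(10, 80, n)
    times = np.minimum(t_event, censor)
    events = (t_event <= censor).astype(int)
    return df, times, events


def test_cox_recovers_generating_hazard_ratio():
    rng = np.random.default_rng(6)
    df, times, events = cox_sim(2000, np.log(2.0), rng)
    fit = bm.fit_cox(df, times, events)
    i = fit.terms.index("diabetes")
    se = np.sqrt(fit.covariance[i, i])
    assert abs(fit.coefficients[i] - np.log(2.0)) < 1.96 * se


def test_cox_null_covariate_near_zero():
    rng = np.random.default_rng(7)
    df, times, events = cox_sim(1500, 0.0, rng)
    fit = bm.fit_cox(df, times, events)
    i = fit.terms.index("COPD")
    se = np.sqrt(fit.covariance[i, i])
    assert abs(fit.coefficients[i]) < 2.5 * se


def test_cox_invariant_to_time_scaling():
    rng = np.random.default_rng(8)
    df, times, events = cox_sim(500, 0.7, rng)
    f1 = bm.fit_cox(df, times, events)
    f2 = bm.fit_cox(df, times * 2.0, events)
    assert np.allclose(f1.coefficients, f2.coefficients, atol=1e-6)


def test_cox_drops_zero_variance_terms_and_requires_events():
    rng = np.random.default_rng(9)
    df, times, events = cox_sim(300, 0.5, rng)
    df["hf_subtype"] = "unknown"   # both subtype dummies zero-variance
    fit = bm.fit_cox(df, times, events)
    assert "subtype_reduced" in fit.dropped_terms
    with pytest.raises(ValueError, match="events"):
        bm.fit_cox(df, times, np.zeros_like(events))


# ---------------------------------------------------------------------------
# pooling
# ---------------------------------------------------------------------------

def _fit(coefs, var):
    k = len(coefs)
    return bm.CoxFit(terms=[f"x{i}" for i in range(k)],
                     coefficients=np.asarray(coefs, float),
                     covariance=np.diag(np.asarray(var, float)))


def test_rubin_hand_fixture():
    pooled = bm.pool_rubin([_fit([1.0], [0.5]), _fit([2.0], [0.5])])
    assert pooled.coefficients[0] == pytest.approx(1.5, abs=1e-12)
    assert pooled.total_variance[0] == pytest.approx(1.25, abs=1e-12)


def test_rubin_identical_fits_and_permutation_invariance():
    fits = [_fit([0.7, -0.2], [0.1, 0.2]) for _ in range(4)]
    pooled = bm.pool_rubin(fits)
    assert np.allclose(pooled.between_variance, 0.0)
    assert np.allclose(pooled.coefficients, [0.7, -0.2])
    rng = np.random.default_rng(10)
    fits2 = [_fit(rng.normal(size=2), [0.1, 0.1]) for _ in range(5)]
    p1 = bm.pool_rubin(fits2)
    p2 = bm.pool_rubin(fits2[::-1])
    assert np.allclose(p1.coefficients, p2.coefficients)
    assert np.allclose(p1.total_variance, p2.total_variance)


def test_rubin_mismatched_terms_error():
    f1 = _fit([1.0], [0.5])
    f2 = bm.CoxFit(terms=["other"], coefficients=np.array([1.0]),
                   covariance=np.array([[0.5]]))
    with pytest.raises(ValueError, match="mismatched"):
        bm.pool_rubin([f1, f2])


def test_cloglog_prediction_pooling():
    pooled = bm.pool_predictions(np.array([[0.9], [0.8]]))
    assert pooled[0] == pytest.approx(0.8578, abs=1e-4)
    same = bm.pool_predictions(np.full((3, 4), 0.6))
    assert np.allclose(same, 0.6)
    rng = np.random.default_rng(11)
    S = rng.uniform(0.05, 0.95, size=(5, 20))
    out = bm.pool_predictions(S)
    assert np.all(out >= S.min(axis=0) - 1e-12)
    assert np.all(out <= S.max(axis=0) + 1e-12)
    with pytest.raises(ValueError, match="strictly"):
        bm.pool_predictions(np.array([[1.0], [0.5]]))


# ---------------------------------------------------------------------------
# end-to-end benchmark under MCAR missingness
# ---------------------------------------------------------------------------

def test_benchmark_close_to_complete_data_cox_under_mcar():
    """With <=30% MCAR missingness the imputed, pooled benchmark should
    discriminate nearly as well as a Cox model on the fully observed data."""
    from seqsurv.evaluation import c_index
    rng = np.random.default_rng(12)
    n = 1200
    df = complete_frame(n, rng)
    lp = (0.03 * (df["age"] - 70) + 0.5 * df["diabetes"]
          + 0.015 * (df["SBP"] - 134) + 0.4 * (df["smoking"] == "yes"))
    rate = 0.02 * np.exp(lp)
    t_event = rng.exponential(1 / rate)
    censor = rng.uniform(20, 100, n)
    times = np.minimum(t_event, censor)
    events = (t_event <= censor).astype(int)
    half = n // 2
    full_valid = df.iloc[half:].copy()

    fit_full = bm.fit_cox(df.iloc[:half], times[:half], events[:half])
    Xv = bm._design_matrix(full_valid, "standard")[fit_full.terms]
    S_full = fit_full.fitter.predict_survival_function(Xv, times=[36.0]).iloc[0]
    c_full = c_index(times[half:], events[half:], 1 - S_full.to_numpy()).estimate

    dfm = df.copy()
    for col, frac in (("SBP", 0.3), ("BMI", 0.25), ("smoking", 0.15)):
        mask = rng.uniform(size=n) < frac
        dfm.loc[mask, col] = np.nan if col != "smoking" else None
    _, risks = bm.run_benchmark(dfm.iloc[:half], times[:half], events[:half],
                                dfm.iloc[half:], times[half:], events[half:],
                                tau=36.0, m=5, seed=3)
    c_imp = c_index(times[half:], events[half:], risks).estimate
    assert c_imp >= c_full - 0.03
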