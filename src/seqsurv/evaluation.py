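"""Censoring-aware model evaluation.

Discrimination (Harrell's concordance, AUPRC at a horizon), calibration
(restricted-cubic-spline smoothed curves with the integrated calibration
index, and the D-calibration statistic), clinical utility (decision curves
with Kaplan–Meier handling of censoring, impact analysis at fixed decision
thresholds), percentile-bootstrap confidence intervals and subgroup
analysis.

Binary-status metrics at a horizon tau share one evaluable-set rule:
patients with an event by tau are positives, patients followed at least tau
without an event are negatives, and patients censored before tau are
excluded. The exclusion (rather than inverse-probability weighting) is a
deliberate, deterministic choice recorded in each result's metadata.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score

logger = logging.getLogger(__name__)

__all__ = ["MetricResult", "CalibrationCurve", "DecisionCurve", "ImpactTable",
           "c_index", "auprc_at_horizon", "calibration_curve_ici",
           "d_calibration", "decision_curve", "impact_analysis",
           "bootstrap_ci", "subgroup_eval", "horizon_status"]

EVALUABLE_RULE = "censored-before-horizon-excluded"


@dataclass
class MetricResult:
    name: str
    estimate: float
    ci_low: float = math.nan
    ci_high: float = math.nan
    n: int = 0
    metadata: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# shared evaluable-set rule
# ---------------------------------------------------------------------------

def horizon_status(times: np.ndarray, events: np.ndarray, tau: float
                   ) -> tuple[np.ndarray, np.ndarray]:
    """(binary status at tau, evaluable mask) under the shared rule."""
    times = np.asarray(times, float)
    events = np.asarray(events).astype(int)
    positive = (events == 1) & (times <= tau)
    negative = times >= tau
    evaluable = positive | negative
    status = np.where(positive, 1, 0)
    return status, evaluable


# ---------------------------------------------------------------------------
# discrimination
# ---------------------------------------------------------------------------

def c_index(times, events, risks) -> MetricResult:
    """Harrell's concordance index.

    A pair (i, j) is comparable iff t_i < t_j and patient i had the event;
    it is concordant if risk_i > risk_j, and risk ties earn half credit.
    """
    times = np.asarray(times, float)
    events = np.asarray(events).astype(int)
    risks = np.asarray(risks, float)
    if not (len(times) == len(events) == len(risks)):
        raise ValueError("times, events and risks must have equal length")
    conc = 0.0
    comp = 0
    # vectorised over the event-anchored rows of the pair matrix
    for i in np.flatnonzero(events == 1):
        later = times > times[i]
        comp += int(later.sum())
        conc += float((risks[i] > risks[later]).sum())
        conc += 0.5 * float((risks[i] == risks[later]).sum())
    if comp == 0:
        raise ValueError("no comparable pairs")
    return MetricResult("c_index", conc / comp, n=len(times),
                        metadata={"comparable_pairs": comp})


def auprc_at_horizon(risks, times, events, tau: float) -> MetricResult:
    """Average precision for event-by-tau status on the evaluable set."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    status, ok = horizon_status(times, events, tau)
    if status[ok].sum() == 0:
        raise ValueError("no positives at this horizon")
    ap = float(average_precision_score(status[ok], np.asarray(risks, float)[ok]))
    return MetricResult("auprc", ap, n=int(ok.sum()),
                        metadata={"evaluable_rule": EVALUABLE_RULE, "tau": tau})


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def _rcs_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Restricted cubic spline basis (Harrell), linear beyond the end knots.

    For 3 knots returns columns [x, C(x)] with one nonlinear term.
    """
    t = np.asarray(knots, float)
    k = len(t)
    span2 = (t[-1] - t[0]) ** 2

    def pos3(u):
        return np.clip(u, 0, None) ** 3

    cols = [x]
    for j in range(k - 2):
        c = (pos3(x - t[j])
             - pos3(x - t[k - 2]) * (t[k - 1] - t[j]) / (t[k - 1] - t[k - 2])
             + pos3(x - t[k - 1]) * (t[k - 2] - t[j]) / (t[k - 1] - t[k - 2]))
        cols.append(c / span2)
    return np.column_stack(cols)


@dataclass
class CalibrationCurve:
    predicted: np.ndarray     # grid of predicted risk
    observed: np.ndarray      # spline-smoothed observed risk on the grid
    ici: float                # mean |smoothed observed − predicted|
    n: int
    metadata: dict = field(default_factory=dict)


def calibration_curve_ici(risks, times, events, tau: float) -> CalibrationCurve:
    """RCS-3-knot logistic calibration curve and integrated calibration index.

    Horizon status is smoothed on the logit of predicted risk with a
    restricted cubic spline (knots at the 10th/50th/90th percentiles) under a
    logistic link, so perfectly calibrated predictions are exactly
    representable; the ICI is the mean absolute difference between the
    smoothed observed risk and the predicted risk over evaluable patients.
    """
    import statsmodels.api as sm
    risks = np.asarray(risks, float)
    status, ok = horizon_status(times, events, tau)
    r, y = risks[ok], status[ok]
    logit = np.log(np.clip(r, 1e-9, 1 - 1e-9) / (1 - np.clip(r, 1e-9, 1 - 1e-9)))
    knots = np.percentile(logit, [10, 50, 90])
    if knots[0] == knots[-1]:
        raise ValueError("degenerate risk distribution: a single value")
    X = sm.add_constant(_rcs_basis(logit, knots), has_constant="add")
    fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    smoothed = np.clip(fit.predict(X), 0.0, 1.0)
    ici = float(np.mean(np.abs(smoothed - r)))
    order = np.argsort(r)
    return CalibrationCurve(predicted=r[order], observed=smoothed[order],
                            ici=ici, n=int(ok.sum()),
                            metadata={"evaluable_rule": EVALUABLE_RULE,
                                      "tau": tau, "knots": knots.tolist()})


def d_calibration(F_values, events, n_bins: int = 10) -> float:
    """Hard-binned D-calibration statistic.

    Predicted CDF values at observed event times should be uniform on [0,1];
    the statistic is the squared deviation of the B bin masses from 1/B,
    summed over bins. A patient censored at CDF value F spreads its unit
    mass uniformly over [F, 1]. Zero iff the binned distribution is exactly
    uniform.
    """
    F = np.asarray(F_values, float)
    events = np.asarray(events).astype(int)
    if F.size == 0:
        raise ValueError("empty input")
    if (F < -1e-9).any() or (F > 1 + 1e-9).any():
        raise ValueError("CDF values must lie in [0,1]")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    mass = np.zeros(n_bins)
    for f, e in zip(F, events):
        if e == 1:
            b = min(int(f * n_bins), n_bins - 1)
            mass[b] += 1.0
        else:
            if f >= 1.0 - 1e-12:
                mass[-1] += 1.0
                continue
            overlap = np.clip(edges[1:] - np.maximum(edges[:-1], f), 0.0, None)
            mass += overlap / (1.0 - f)
    mass /= len(F)
    return float(np.sum((mass - 1.0 / n_bins) ** 2))


# ---------------------------------------------------------------------------
# decision curves & impact
# ---------------------------------------------------------------------------

@dataclass
class DecisionCurve:
    thresholds: np.ndarray
    net_benefit: np.ndarray
    net_benefit_all: np.ndarray
    net_benefit_none: np.ndarray
    n: int
    metadata: dict = field(default_factory=dict)


def _km_event_prob(times: np.ndarray, events: np.ndarray, tau: float) -> float:
    """1 − S_KM(tau) within a group (empirical proportion if no censoring)."""
    from lifelines import KaplanMeierFitter
    if len(times) == 0:
        return 0.0
    km = KaplanMeierFitter()
    km.fit(times, events)
    return 1.0 - float(km.predict(tau))


def decision_curve(risks, times, events, tau: float,
                   thresholds=None) -> DecisionCurve:
    """Net benefit across decision thresholds, censoring handled by KM.

    NB(p) = TP/n − FP/n · p/(1−p), with the event probability among
    predicted positives estimated by Kaplan–Meier at tau within that group,
    so censored patients contribute their observed follow-up.
    """
    thresholds = np.asarray(
        np.arange(0.05, 0.96, 0.05) if thresholds is None else thresholds, float)
    if (thresholds >= 1).any() or (thresholds <= 0).any():
        raise ValueError("thresholds must lie strictly inside (0,1)")
    risks = np.asarray(risks, float)
    times = np.asarray(times, float)
    events = np.asarray(events).astype(int)
    n = len(risks)
    p_all = _km_event_prob(times, events, tau)
    nb_model, nb_all = [], []
    for p in thresholds:
        odds = p / (1.0 - p)
        pos = risks >= p
        if pos.any():
            p_event = _km_event_prob(times[pos], events[pos], tau)
            frac_pos = pos.mean()
            nb_model.append(frac_pos * (p_event - (1.0 - p_event) * odds))
        else:
            nb_model.append(0.0)
        nb_all.append(p_all - (1.0 - p_all) * odds)
    return DecisionCurve(thresholds=thresholds,
                         net_benefit=np.asarray(nb_model),
                         net_benefit_all=np.asarray(nb_all),
                         net_benefit_none=np.zeros_like(thresholds),
                         n=n, metadata={"tau": tau})


@dataclass
class ImpactTable:
    thresholds: tuple
    rows: dict           # threshold -> {TP, FP, FN, TN, PPV, sensitivity}
    n_evaluable: int
    metadata: dict = field(default_factory=dict)


def impact_analysis(risks, times, events, tau: float,
                    thresholds=(0.25, 0.5, 0.75)) -> ImpactTable:
    """Confusion counts, PPV and sensitivity at fixed decision thresholds."""
    risks = np.asarray(risks, float)
    status, ok = horizon_status(times, events, tau)
    if not ok.any():
        raise ValueError("empty evaluable set")
    r, y = risks[ok], status[ok]
    rows = {}
    for thr in thresholds:
        pred = r >= thr
        tp = int((pred & (y == 1)).sum())
        fp = int((pred & (y == 0)).sum())
        fn = int((~pred & (y == 1)).sum())
        tn = int((~pred & (y == 0)).sum())
        rows[thr] = {"TP": tp, "FP": fp, "FN": fn, "TN": tn,
                     "PPV": tp / (tp + fp) if tp + fp else math.nan,
                     "sensitivity": tp / (tp + fn) if tp + fn else math.nan}
    return ImpactTable(thresholds=tuple(thresholds), rows=rows,
                       n_evaluable=int(ok.sum()),
                       metadata={"evaluable_rule": EVALUABLE_RULE, "tau": tau})


def impact_comparison(table_a: ImpactTable, table_b: ImpactTable) -> dict:
    """FP/FN differences (a − b) and percentage changes per threshold."""
    out = {}
    for thr in table_a.thresholds:
        a, b = table_a.rows[thr], table_b.rows[thr]
        out[thr] = {
            "FP_diff": a["FP"] - b["FP"], "FN_diff": a["FN"] - b["FN"],
            "FP_pct_change": 100.0 * (a["FP"] - b["FP"]) / b["FP"] if b["FP"] else math.nan,
            "FN_pct_change": 100.0 * (a["FN"] - b["FN"]) / b["FN"] if b["FN"] else math.nan,
            "PPV_diff": a["PPV"] - b["PPV"],
            "sensitivity_diff": a["sensitivity"] - b["sensitivity"]}
    return out


# ---------------------------------------------------------------------------
# uncertainty & subgroups
# ---------------------------------------------------------------------------

def bootstrap_ci(metric_fn, data: tuple, n_boot: int = 200,
                 seed: int = 0, name: str = "metric") -> MetricResult:
    """Percentile bootstrap over patient-level resamples.

    ``metric_fn(*resampled_arrays) -> float``; resamples on which the metric
    is undefined are skipped, erroring if more than half fail.
    """
    arrays = [np.asarray(a) for a in data]
    n = len(arrays[0])
    rng = np.random.default_rng(seed)
    point = float(metric_fn(*arrays))
    stats = []
    failures = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            stats.append(float(metric_fn(*(a[idx] for a in arrays))))
        except (ValueError, ZeroDivisionError):
            failures += 1
    if failures > n_boot // 2:
        raise ValueError("metric undefined on most bootstrap resamples")
    lo, hi = np.percentile(stats, [2.5, 97.5])
    return MetricResult(name, point, float(lo), float(hi), n=n,
                        metadata={"n_boot": n_boot, "failures": failures})


def subgroup_eval(metric_fn, data: tuple, groups: np.ndarray,
                  min_size: int = 50) -> dict[str, MetricResult]:
    """Metric per subgroup plus signed deviation from the overall estimate."""
    arrays = [np.asarray(a) for a in data]
    overall = float(metric_fn(*arrays))
    out = {"overall": MetricResult("overall", overall, n=len(arrays[0]))}
    groups = np.asarray(groups)
    for g in np.unique(groups):
        mask = groups == g
        if mask.sum() < min_size:
            logger.warning("subgroup %r has %d < %d evaluable patients; skipped",
                           g, int(mask.sum()), min_size)
            continue
        try:
            est = float(metric_fn(*(a[mask] for a in arrays)))
        except ValueError as exc:
            logger.warning("subgroup %r skipped: %s", g, exc)
            continue
        out[str(g)] = MetricResult(str(g), est, n=int(mask.sum()),
                                   metadata={"deviation": est - overall})
    return out
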