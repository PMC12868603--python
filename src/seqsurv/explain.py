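"""Integrated-gradients attribution of predicted risk to encounter tokens.

Each encounter token's contribution to the horizon risk F(tau) = 1 − S(tau)
is the path integral of the gradient of F with respect to the token's
code-channel embedding, along the straight line from a reference sequence to
the actual one. The reference replaces every encounter embedding with the
PAD embedding — the model's native representation of absence — while the
age and position channels and the attention mask are left untouched, so the
attribution isolates what the recorded codes contribute. Scores satisfy the
completeness property: they sum to F(actual) − F(reference) up to the
Riemann discretisation of the path.

For a patient with repeated recordings of the same code, the code-level
score is the maximum over its occurrences. Population summaries average
per-patient scores over carriers of each code (codes in at least 1% of
patients by default), with normal-approximation confidence intervals, and
can be stratified by sex, by age at the first recording of the code, or by
time from that first recording to baseline.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from datetime import date

import numpy as np

from .autodiff import Tensor, embedding_lookup
from .corpus import (DAYS_PER_MONTH, PAD, PREDICT, PatientRecord,
                     TokenSequence, Vocabulary)
from .model import ModelParams, _cumhaz_at_times, _n_panels, embed, encode

logger = logging.getLogger(__name__)

__all__ = ["AttributionRecord", "CodeSummary", "integrated_gradients",
           "per_patient_code_attribution", "population_summary",
           "stratified_summary", "attribute_patient", "AGE_BANDS", "TIME_BANDS"]

AGE_BANDS = ((50, 59), (60, 69), (70, 79), (80, math.inf))
TIME_BANDS = {"<1y": (0.0, 12.0), "1-5y": (12.0, 60.0),
              "5-10y": (60.0, 120.0), ">10y": (120.0, math.inf)}


@dataclass
class AttributionRecord:
    patient_id: str
    code: str
    modality: str
    score: float                    # signed attribution of F(tau)
    first_recording_age: float      # years
    months_before_baseline: float   # from first recording to baseline


@dataclass
class CodeSummary:
    code: str
    mean: float
    ci_low: float
    ci_high: float
    n_patients: int
    prevalence: float


# ---------------------------------------------------------------------------
# per-sequence attribution
# ---------------------------------------------------------------------------

def integrated_gradients(params: ModelParams, sequence: TokenSequence,
                         tau: float | None = None,
                         steps: int = 128) -> np.ndarray:
    """Per-token attribution scores for one sequence.

    The gradient of F(tau) with respect to the code-channel embedding input
    is averaged over ``steps`` points on the straight path from the PAD
    reference, then contracted with (embedding − reference) and summed over
    the embedding dimensions, yielding one signed scalar per token slot.
    Padding and the PREDICT slot score exactly zero.
    """
    cfg = params.config
    tau = cfg.horizon if tau is None else tau
    if not all(np.isfinite(t.data).all() for t in params.tensors.values()):
        raise ValueError("model parameters contain non-finite values")
    L = sequence.code_ids.shape[0]
    actual = params["emb_code"].data[sequence.code_ids]          # (L, E)
    ref_ids = np.full(L, 0, dtype=np.int64)                      # PAD everywhere
    ref_ids[sequence.predict_index] = sequence.code_ids[sequence.predict_index]
    reference = params["emb_code"].data[ref_ids]
    delta = actual - reference

    # composite two-point Gauss-Legendre quadrature along the path
    # (4th-order accurate, so the completeness identity holds tightly and
    # tightens further as the step count grows)
    m = max(1, steps // 2)
    centres = (np.arange(m) + 0.5) / m
    offset = 1.0 / (2.0 * math.sqrt(3.0) * m)
    alphas = np.sort(np.concatenate([centres - offset, centres + offset]))
    alphas = alphas.reshape(-1, 1, 1)
    steps = 2 * m   # actual number of path evaluations
    path = reference[None] + alphas * delta[None]                # (2m, L, E)
    code_emb = Tensor(path, requires_grad=True)

    ids = {
        "age": np.broadcast_to(sequence.age_ids, (steps, L)),
        "pos": np.broadcast_to(sequence.position_ids, (steps, L)),
        "mask": np.broadcast_to(sequence.attention_mask, (steps, L)),
    }
    latents = embed(params, None, ids["age"], ids["pos"], code_emb=code_emb)
    h = encode(params, latents, np.ascontiguousarray(ids["mask"]),
               np.full(steps, sequence.predict_index))
    n = _n_panels(tau, cfg.max_time_step)
    cum, _ = _cumhaz_at_times(params, h, np.full(steps, float(tau)), n_panels=n)
    F = 1.0 - (-cum).exp()
    F.sum().backward()
    avg_grad = code_emb.grad.mean(axis=0)                        # (L, E)
    scores = (delta * avg_grad).sum(axis=-1)
    scores[sequence.attention_mask == 0] = 0.0
    return scores


def risk_from_code_embedding(params: ModelParams, sequence: TokenSequence,
                             code_emb_rows: np.ndarray,
                             tau: float | None = None) -> float:
    """F(tau) with the code channel forced to explicit embedding rows
    (used by the completeness check against the reference sequence)."""
    from .autodiff import no_grad
    cfg = params.config
    tau = cfg.horizon if tau is None else tau
    L = sequence.code_ids.shape[0]
    with no_grad():
        latents = embed(params, None, sequence.age_ids.reshape(1, L),
                        sequence.position_ids.reshape(1, L),
                        code_emb=Tensor(code_emb_rows.reshape(1, L, -1)))
        h = encode(params, latents, sequence.attention_mask.reshape(1, L),
                   np.array([sequence.predict_index]))
        n = _n_panels(tau, cfg.max_time_step)
        cum, _ = _cumhaz_at_times(params, h, np.array([float(tau)]), n_panels=n)
        return float(1.0 - np.exp(-cum.data[0]))


def per_patient_code_attribution(token_scores: np.ndarray,
                                 sequence: TokenSequence) -> dict[str, float]:
    """Collapse token scores to one score per distinct code: the maximum
    over the code's occurrences. Special tokens never appear."""
    out: dict[str, float] = {}
    for slot, code in enumerate(sequence.codes):
        if not code or code in (PAD, PREDICT) or not sequence.attention_mask[slot]:
            continue
        s = float(token_scores[slot])
        if code not in out or s > out[code]:
            out[code] = s
    return out


def attribute_patient(params: ModelParams, patient: PatientRecord,
                      baseline: date, sequence: TokenSequence,
                      tau: float | None = None,
                      steps: int = 128) -> list[AttributionRecord]:
    """Integrated-gradients attribution for one patient, annotated with the
    first-recording age and time-to-baseline of each code."""
    scores = integrated_gradients(params, sequence, tau=tau, steps=steps)
    code_scores = per_patient_code_attribution(scores, sequence)
    first: dict[str, date] = {}
    modality: dict[str, str] = {}
    for enc in patient.encounters:
        if enc.date > baseline:
            continue
        if enc.code not in first or enc.date < first[enc.code]:
            first[enc.code] = enc.date
        modality.setdefault(enc.code, enc.modality)
    records = []
    for code, score in code_scores.items():
        d0 = first.get(code, baseline)
        records.append(AttributionRecord(
            patient_id=patient.patient_id, code=code,
            modality=modality.get(code, "diagnosis"), score=score,
            first_recording_age=patient.age_years(d0),
            months_before_baseline=(baseline - d0).days / DAYS_PER_MONTH))
    return records


# ---------------------------------------------------------------------------
# population summaries
# ---------------------------------------------------------------------------

def population_summary(records: list[AttributionRecord], n_patients: int,
                       min_prevalence: float = 0.01) -> list[CodeSummary]:
    """Mean contribution per code over its carriers, ranked descending.

    Codes carried by fewer than ``min_prevalence`` of patients are dropped;
    95% confidence intervals use the normal approximation.
    """
    by_code: dict[str, list[float]] = {}
    for r in records:
        by_code.setdefault(r.code, []).append(r.score)
    out = []
    for code, scores in by_code.items():
        n = len(scores)
        prev = n / n_patients
        if prev < min_prevalence:
            continue
        mean = float(np.mean(scores))
        se = float(np.std(scores, ddof=1) / math.sqrt(n)) if n > 1 else 0.0
        out.append(CodeSummary(code=code, mean=mean, ci_low=mean - 1.96 * se,
                               ci_high=mean + 1.96 * se, n_patients=n,
                               prevalence=prev))
    if not out:
        raise ValueError("no codes pass the prevalence filter")
    return sorted(out, key=lambda s: -s.mean)


def _stratum_key(record: AttributionRecord, strata: str) -> str | None:
    if strata == "sex":
        raise ValueError("sex stratification needs patient sex; use the "
                         "sex_by_patient argument of stratified_summary")
    if strata == "age":
        for lo, hi in AGE_BANDS:
            if lo <= record.first_recording_age <= hi:
                return f"{lo}-{hi}" if math.isfinite(hi) else f">={lo}"
        return None
    if strata == "time_to_baseline":
        for name, (lo, hi) in TIME_BANDS.items():
            if lo <= record.months_before_baseline < hi:
                return name
        return None
    raise ValueError(f"unknown stratification {strata!r}")


def stratified_summary(records: list[AttributionRecord], n_patients: int,
                       strata: str, min_prevalence: float = 0.01,
                       sex_by_patient: dict[str, str] | None = None
                       ) -> dict[str, list[CodeSummary]]:
    """Population summary within strata of sex, first-recording age band, or
    time-to-baseline band (keyed by the FIRST recording of each code)."""
    groups: dict[str, list[AttributionRecord]] = {}
    for r in records:
        if strata == "sex":
            if sex_by_patient is None:
                raise ValueError("sex stratification requires sex_by_patient")
            key = sex_by_patient.get(r.patient_id)
        else:
            key = _stratum_key(r, strata)
        if key is None:
            continue
        groups.setdefault(key, []).append(r)
    out = {}
    for key, recs in sorted(groups.items()):
        try:
            out[key] = population_summary(recs, n_patients, min_prevalence)
        except ValueError:
            logger.warning("stratum %r empty after the prevalence filter; "
                           "skipped", key)
    return out
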