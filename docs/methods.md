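# Methods

This note records the models, algorithms and numerical choices behind
`seqsurv`, and what the synthetic cohorts its tests run on do and do not
establish about real data.

## Problem setting

The package addresses dynamic risk prediction for patients with a chronic
condition (the motivating application is heart failure): given everything in
a patient's coded record up to an index date — diagnoses, medications,
procedures, each with a calendar date — predict the probability of death
within a fixed horizon τ (12 or 36 months by default). The index date is not
anchored to diagnosis: it is drawn uniformly from each patient's eligibility
window (first qualifying diagnosis to the earliest of death, loss to
follow-up and the administrative study end, end-exclusive so follow-up is
strictly positive). A patient who dies on the day of diagnosis has an empty
window and is excluded. This trains and evaluates the model across the whole
spectrum of disease duration rather than at a single landmark.

## Data model and pre-processing

Raw records are harmonised before tokenisation:

* **Diagnoses** → level-4 ICD-10: the three-character category plus at most
  one character after the decimal point (`I50.19` → `I50.1`); dotted and
  undotted dialects are both accepted and dot-normalised.
* **Medications** → BNF section (first four digits) where a user-supplied
  BNF mapping covers the product code, otherwise the virtual therapeutic
  moiety (VTM) code from a second mapping table; anything unmappable becomes
  `UNK` with a logged warning.
* **Procedures** are used as recorded.
* Codes carried by fewer than 0.1% of patients are excluded from the
  vocabulary (threshold `ceil(0.001·n)` distinct carriers).

Sequences end in a `PREDICT` token. Each token carries three channels: the
code id, the integer age at the encounter (computed against July 1 of the
birth year — the convention when only a birth year is recorded), and a visit
number (all encounters on one calendar day form one visit; the `PREDICT`
token takes the next visit number and the age at baseline). Histories longer
than `max_len − 1` keep the most recent encounters; visit numbers are then
renumbered from 1 over what is kept so position ids stay inside the learned
range. Encounters dated on the baseline day itself are included by default
(configurable). Same-date encounters keep their input order (stable sort),
making tokenisation deterministic.

Survival labels are months from baseline (30.4375 days/month) to death if
death precedes both loss to follow-up and the study end, otherwise censored
months to that earlier date.

## The transformer survival model

**Embedding.** The three E-wide channels are concatenated and projected
3E → E by a learned affine map followed by `tanh`. The BEHRT-style ablation
(`embedding_mode="sum"`) adds the channels instead.

**Encoder.** `n_layers` post-norm transformer blocks (multi-head
self-attention, then a GELU feed-forward of width `ffn_mult·E`, each with a
residual connection and LayerNorm). Padding slots are excluded as attention
keys in every layer, so representations are independent of padding content
and batch composition. The encoder state at the `PREDICT` slot is the
patient representation h. GELU (tanh form) rather than ReLU keeps the
network C¹-smooth, which the attribution quadrature (below) relies on.

**Survival head.** The hazard λ(t, h) is a one-hidden-layer network
(`tanh` hidden layer, softplus output, input [t/τ, h]); softplus keeps
λ > 0 with smooth gradients. The cumulative hazard solves

    dΛ/dt = λ(t, h),  Λ(0) = 0,

integrated by a fixed-step Runge–Kutta scheme. Because the right-hand side
does not depend on Λ, each RK4 step reduces exactly to composite Simpson
quadrature; the whole grid of hazard evaluations for a batch is one network
pass. Then S(t) = exp(−Λ(t)) and the reported risk is F(τ) = 1 − S(τ).
Inference and all closed-form oracles use a step of at most 0.5 months, with
an optional step-halving self-check; the training loss uses a 2-month step
(capped at 64 panels), a purely numerical economy — for the smooth hazards
the head can express, the Simpson error at that step is orders of magnitude
below the sampling noise of the likelihood, and for a constant hazard the
rule is exact at any step. Fixed steps keep every result bit-reproducible.
The scheme is accurate to ~1e-4 for hazards with bounded derivatives; it is
*not* suited to hazards singular at t = 0 (e.g. Weibull with shape < 1),
which the step-halving check flags.

**Loss.** The censored negative log-likelihood

    NLL = −mean_i [ δ_i·log λ(t_i) + log S(t_i) ]

plus α times a differentiable D-calibration surrogate (XCal). D-calibration
demands that predicted CDF values F(t_i) at observed event times be uniform
on [0, 1]. The surrogate assigns each uncensored observation soft
memberships over B equal-width bins via temperature-γ sigmoids; an
observation censored at CDF value F(c) spreads its residual mass uniformly
over [F(c), 1]. The penalty is the squared deviation of the bin masses from
1/B, summed over bins. Defaults: B = 20, α = 1, γ = 50. γ trades bin
sharpness against gradient flow: at γ = 50 the sigmoid transition width
(≈4/γ) is about 1.6 bin widths, which keeps the penalty informative while
leaving usable gradients everywhere; very sharp settings (γ ≳ 10³) make the
surrogate a near-hard histogram whose gradient vanishes almost everywhere
and train no better than α = 0. Setting `use_xcal=False` (or α = 0)
reproduces pure-NLL training exactly.

**Training.** Adam on mini-batches (reference recipe: batch 32, learning
rate 3e-3 with cosine decay over the epoch budget), with an exponential
moving average of the weights (decay 0.995 per step) providing the
end-of-epoch checkpoint candidates; a held-out 5% of the training set is
scored at the end of every epoch and the candidate with the best loss is
returned, with early stopping after `patience` epochs without improvement.
The EMA matters on cohorts of a few thousand patients: the raw trajectory's
held-out concordance fluctuates by ±0.02 between epochs and the 5% split is
too small to pick the peak reliably, while the averaged weights track the
trajectory's centre. Age and visit-position embedding tables start at zero
so the code channel carries the signal from the first step; the tables grow
only as their gradients demand. Optional encounter-token dropout
(`token_dropout`) is available but off by default — when each code appears
once per record, dropping tokens deletes exactly the presence information
the model needs. Everything is seeded; two runs with the same config and
seed are bit-identical.

**Transfer.** Fine-tuning copies embedding rows for codes shared between the
source and target vocabularies, initialises rows for new codes fresh, copies
all other weights, and continues training on the target dataset with a 10%
end-of-epoch split. Zero epochs returns the transferred parameters unchanged.

## The Cox benchmark

A pragmatic EHR adaptation of an established heart-failure risk score,
without the echocardiographic variable that routine records lack (an HF
subtype categorical stands in for it). Baseline covariates: windowed means
(36 months up to baseline) of SBP, creatinine, BMI and — in the extended
variant — sodium; last known smoking status and NYHA class in that window;
ever-before-baseline flags for diseases and procedures; sex; age; HF
duration ≥ 18 months; HF subtype, with age×subtype and SBP×subtype
interactions. The extended variant adds AF, stroke, MI, PCI and CABG flags.

Missing values are multiply imputed (m = 5, 10 chained-equation sweeps).
Continuous variables use predictive mean matching with 5 donors and a normal
draw of the regression coefficients around the least-squares fit (covariance
regularised by a tiny ridge so collinear predictors do not break the draw);
categorical variables use multinomial logistic sampling fitted on the
complete cases each sweep (no posterior draw of its coefficients — a known
simplification relative to fully Bayesian MICE that slightly understates
between-imputation variance for those variables). All model variables plus
the event indicator and the Nelson–Aalen cumulative-hazard estimate at the
observed time enter every imputation model, the standard way to keep the
imputations compatible with the survival outcome. Derivation and validation
sets are imputed separately. One Cox model (partial likelihood, Breslow
baseline, lifelines) is fitted per completed derivation set; zero-variance
design columns (e.g. a subtype absent from a synthetic cohort) are dropped
and recorded. Coefficients pool by Rubin's rules (total variance
W + (1 + 1/m)B); survival predictions pool on the complementary log-log
scale, exp(−exp(mean log(−log S))), after clipping S into (ε, 1−ε).
NYHA is treated as nominal in the imputation model (its ordinality is weak
information relative to its extreme missingness in routine records).
Continuous terms enter linearly with the two stated interactions.

## Evaluation

All horizon-status metrics (AUPRC, calibration smoothing, impact analysis)
share one evaluable-set rule: events by τ are positives, patients followed
at least τ without an event are negatives, patients censored before τ are
excluded. Exclusion rather than inverse-probability weighting is a
deliberate choice — deterministic, assumption-free, and flagged in every
result's metadata; under heavy informative censoring it can bias these
binary metrics, which is why the rank-based C-index (computed over all
follow-up, Harrell's convention, ties in risk scoring ½) is the primary
discrimination measure.

Calibration curves smooth horizon status on the logit of predicted risk
with a 3-knot restricted cubic spline (knots at the 10th/50th/90th
percentiles) under a logistic link; fitting on the logit scale makes
perfectly calibrated predictions exactly representable. The ICI is the mean
absolute difference between smoothed observed and predicted risk. The hard
D-calibration statistic is the squared deviation of the B = 10 bin masses
of F(t_i) from uniform, censored mass spread above F(c).

Decision curves use net benefit NB(p) = TP/n − FP/n · p/(1−p), with the
event probability among predicted positives estimated by Kaplan–Meier at τ
within that group, so censored patients contribute follow-up; without
censoring this reduces exactly to the count-based net benefit. Impact
analysis reports confusion counts, PPV and sensitivity at the 25/50/75%
thresholds. Confidence intervals are percentile bootstrap over patients
(B = 200, seeded); subgroup analysis reports each group's metric and its
signed deviation from the overall estimate, skipping groups below 50
evaluable patients.

## Attribution

Integrated gradients at the code-embedding layer: the reference sequence
replaces every encounter embedding with the PAD embedding (the model's
native representation of absence) while ages, positions, the attention mask
and the PREDICT slot stay untouched. Scores are the path integral of
∂F(τ)/∂e contracted with (e − reference), summed over embedding dimensions —
one signed scalar per token. The path integral uses composite two-point
Gauss–Legendre quadrature (4th-order); with the GELU encoder the integrand
is smooth and the completeness identity |Σ scores − (F(x) − F(ref))| holds
to ~1e-9 relative at 128 evaluations. Padding and PREDICT slots score
exactly zero. Repeated recordings of a code collapse to the maximum score
over occurrences. Population summaries average per-patient scores over
carriers (codes in ≥1% of patients), with normal-approximation 95% CIs,
optionally stratified by sex, by age band at the code's first recording
(50–59 / 60–69 / 70–79 / ≥80) or by time from first recording to baseline
(<1y / 1–5y / 5–10y / >10y).

## The synthetic cohort generator

The generator is the package's ground-truth oracle, not a disease model.
Patients enter at an age uniform on 40–90 on a uniform calendar day of the
study period (2010–2019 by default); the entry day is also the first
qualifying diagnosis. Visits arrive as a homogeneous Poisson process at 6
per patient-year. Each code is first recorded at a visit with probability
0.03; by default a code enters the record exactly once, so the token stream
shows precisely the set of distinct codes the simulated hazard depends on.
Chronic re-recording (the same code recurring at later visits, as it does
in routine data) is available per code via `chronic_rerecord_prob` and is
exercised in the tests, but stays off in the default conditions: the
simulated hazard is presence-based, so re-recorded duplicates are pure
frequency noise for an attention-pooling model — a property worth studying
deliberately, not a sensible default for a ground-truth oracle. The default
vocabulary has 30 codes cycling through the three modalities, 5 of them
causal with |β| in [0.5, 1.5] and alternating sign. The true linear
predictor at baseline is η = Σ β_c·w(Δt_c) over distinct codes in history,
with w ≡ 1 or an exponential-decay weight 2^(−Δt/half-life); event times
are exponential with rate λ₀·exp(η) per month after baseline (λ₀ = 0.02),
dropout is an independent exponential (0.01/month), and administrative
censoring falls at the study end. With these defaults roughly 35–40% of
patients die in follow-up and the causal codes are carried by about a third
of patients — enough carriers that the code effects are statistically
identifiable at the cohort sizes the tests use (a Cox fit on the true
indicators recovers each β and comes within ~0.02 of the oracle C-index).
Measurements (SBP, BMI, creatinine, sodium, smoking, NYHA) are drawn around
patient-level means at visit dates and withheld wholesale per patient at
the missingness rates reported for the motivating UK cohort (BMI 26.7%,
smoking 14.0%, SBP 4.0%, creatinine 9.1%, NYHA 96.6%, sodium 9.7%).

What the generator deliberately does not emulate: real code co-occurrence
and progression structure, time-varying post-baseline hazards,
measurement–outcome dependence (measurements are pure noise for the
outcome), informative censoring, and realistic vocabulary sizes (real
cohorts carry thousands of codes, the tests use tens). Passing tests
therefore demonstrate that the machinery recovers known structure under the
stated assumptions — constant post-baseline hazard per patient,
non-informative censoring — not that the model attains any particular
performance on clinical data.

### Resolution of temporal attribution contrasts

The shipped recency experiment trains a small ensemble (three independently
seeded models on one cohort) and averages each patient-code attribution
across the ensemble before stratifying — a single small model's band
estimates carry training noise comparable to the outer-band contrasts. Even
so, the model's only recency signal is the learned per-year age embedding,
and at a few thousand patients it resolves a shared, saturating recency
discount rather than fully code-specific temporal profiles: the
<1y → 1–5y → 5–10y gradient is large and reproduces under any conditions we
tried, while the 5–10y vs >10y ordering sits at the resolution limit and
depends on the simulated cohort. Distinguishing a genuinely persistent
effect from a decayed one more than a decade back is exactly the kind of
contrast that needs population-scale records.

## Problem sizes used in the shipped tests

The test suite and acceptance script favour the smallest cohorts at which
each property is decidable: n = 2000 (+1000 fresh test patients) for
parameter recovery with the reference tiny architecture (E = 32, 2 layers,
2 heads, max_len 64, ≤20 epochs); n ≈ 600–800 and 1–2-layer models for the
calibration and transfer comparisons, which are paired contrasts and need
fewer patients; n = 5000 outcome draws for the large-sample ICI check,
which involves no training. Oracle-equivalence checks run at n ≤ 50 against
brute-force enumeration.

## Known limitations

* CPU-only numpy engine: cohorts beyond ~10⁴ patients or vocabularies
  beyond ~10³ codes are impractical to train here.
* The evaluable-set rule biases horizon metrics under heavy censoring
  (by design, documented above).
* PMM with a ridge-regularised coefficient draw and complete-case
  multinomial sampling is an approximation to fully Bayesian chained
  equations.
* The ODE head assumes hazards smooth in t; singular hazards (Weibull
  shape < 1) are outside the integrator's contract and are flagged by the
  step-halving check rather than silently mis-integrated.
* Attribution scores are reported for the risk F(τ) at one horizon; they
  are not causal effects.
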