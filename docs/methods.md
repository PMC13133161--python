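# Methods

This note documents the statistical model, the federated computation
scheme, the synthetic-cohort design and the numerical choices made in
`fedsurv`, together with what the package's tests do and do not
demonstrate about real data.

## Endpoints and outcome derivation

Three right-censored endpoints are derived per patient from raw event
fields, all measured in months from the first radiotherapy fraction:

- **OS** — death from any cause; censored at last clinical follow-up.
- **LRC** — locoregional failure; censored at the earliest of death,
  abdominoperineal resection for non-disease reasons, distant
  metastasis, or last follow-up.
- **FFDM** — distant metastasis; censored at the earliest of
  locoregional recurrence, death, or last follow-up.

When a censoring cause precedes the endpoint's event time, the patient
is censored at the earlier time: the subject leaves observation for
that endpoint before the event could be recorded. This convention
keeps LRC and FFDM times bounded by the OS time and makes the derived
outcomes well-defined for any combination of recorded fields. An event
time exceeding the recorded follow-up raises a data-consistency error
rather than being silently clipped.

## Covariate encoding

The primary model uses eleven encoded terms (ten for FFDM, which omits
radiotherapy technique and excludes patients metastatic at baseline):
dummy codes with reference level 0 (male, T1-2, N0, SCC, 3D-CRT, no
chemotherapy), age in decades (years/10), log10 of the gross tumour
volume in cm³, prescribed dose as EQD2/10 (EQD2 computed with
α/β = 10 Gy: `D·(d + α/β)/(2 + α/β)`), and three chemotherapy dummies
(mitomycin-based, cisplatin-based, other) relative to no chemotherapy.
Mitomycin- or cisplatin-containing doublets are collapsed into their
base-agent groups. Continuous terms are deliberately *not*
mean-centred, so the reference covariate vector — categoricals 0, age
term 3.5, log10 GTV 0.02572, dose term 4.0 — is interpretable
literally. (Note: 10^0.02572 ≈ 1.061 cm³; the conventional "1.1 cm³"
gloss of this reference value is a rounding.) A configuration switch
(`ModelConfig.dose_log10`) replaces the linear dose term with
log10(EQD2) for sensitivity analyses; the linear form is the default.

Missing tumour volume is the only field imputed: a centre with missing
GTVs fills them with the median of the other centres' per-centre mean
GTVs, exchanging only scalar means. Missing categorical data are
rejected, not imputed.

## Federated Breslow Cox fitting

Ties are handled with the Breslow approximation throughout. Each node
evaluates, on a shared grid of global distinct event times, the local
sums `d_k, s_k, S0_k, S1_k, S2_k` over its own risk sets at the current
coefficients (see README for the formulas). The server aggregates
these across nodes and performs Newton–Raphson with step-halving; the
score, information and partial log-likelihood it computes are exactly
those of the pooled cohort, so the federated estimate coincides with a
centralised Breslow fit for every partition of the data. This
gradient/Hessian-sharing scheme is the only aggregation style with
that exactness guarantee, which is why it is implemented here rather
than any form of coefficient averaging.

Sharing the event-time grid in clear is the privacy–utility trade-off
this design makes explicit: exact equivalence requires a common grid,
and grid times reveal when events occurred (though not to whom). All
exchanged payloads are validated against a schema whitelist and logged
by an append-only audit object; nothing with per-patient granularity
is representable in the schemas.

Convergence defaults: start at β = 0; stop when the largest
coefficient change is below 1e-8 *and* the relative log-likelihood
change is below 1e-10; at most 50 iterations and 20 step-halvings.
A singular information matrix triggers one ridge-regularised retry
(ridge 1e-8 · tr(I)/p) before failing. Monotone likelihood
(separation) is declared when a coefficient exceeds 10 in absolute
value while the score stays bounded away from zero, or — the numeric
plateau form, where relative hazards underflow and the score vanishes
spuriously — while its standard error exceeds 5. Such fits raise an
error rather than returning an absurd estimate; at the default cohort
size this occurs in a few percent of simulated cohorts, essentially
always because the ~1%-prevalence cisplatin group drew zero events.

Standard errors come from the inverse observed information at the
optimum; hazard-ratio tables report Wald 95% intervals
`exp(β ± 1.96·se)` and flag a factor prognostic when its interval
excludes 1.

The pooled oracle used in tests (`fit_pooled_cox_oracle`) delegates the
coefficient estimate to scikit-survival's Breslow implementation, an
independent code path; lifelines (Efron ties) provides a second
cross-check on tie-free data, where the two partial likelihoods
coincide.

## Prediction

The cumulative baseline hazard is the Breslow step function
`ΔΛ0(t_k) = d_k / Σ_nodes S0_k(β̂)`, anchored at the encoded-zero
covariate vector and built from one additional audited node round.
Survival between event times is a right-continuous step; no smoothing
is applied. Individual predictions use `S(t|x) = S0(t)^exp(β̂'x)`;
reference outcome rates evaluate this at the reference vector at 24,
36 and 60 months, and horizons beyond the last observed event time
return the last step's value with an explicit extrapolation flag.

Risk groups split patients at the global mean of the predicted 3-year
outcome rates (computed by exchanging per-centre sums and counts
only): below the mean is "high risk". The split uses the predicted
rate rather than the linear predictor so that the threshold has a
direct clinical reading; the two orderings are identical, so the
grouping is the same either way.

## Validation

Discrimination uses Harrell's c-index with the linear predictor as the
risk score: over comparable pairs (the earlier time is an event,
strictly earlier), the fraction where the earlier-failing patient has
the higher score, ties in score counting 1/2. The implementation is a
vectorised full pair enumeration and is tested for exact equality
against an independent brute-force loop and against scikit-survival on
tie-free data. Per-centre c-indices are combined by a mean weighted by
centre cohort size (event-count weighting would be a defensible
alternative; size weighting matches how the cohort's other summary
statistics are combined).

Leave-one-centre-out validation refits the federation on the remaining
centres and scores each held-out centre locally; only (c-index, n)
summaries leave the node, and folds whose held-out centre has no
events, no comparable pairs, or whose training likelihood has no
finite maximum are skipped with a warning. External validation scores
frozen models on the validation centres with the same machinery.
Potential follow-up is summarised by the reverse Kaplan-Meier
estimator (censoring treated as the event). Calibration at 36 months
compares, per centre and risk group, the mean predicted rate with the
observed Kaplan-Meier rate and its Greenwood 95% band.

## Synthetic cohort design

The generator emulates the structure of a 16-centre cohort (14
training centres, n = 1428; 2 validation centres, n = 277; the second
training centre has n = 210 for single-centre comparator experiments).
Covariate margins follow the published cohort composition: 70% female;
age N(62.4, 11.3²) truncated to [21, 94]; 43% T3-4; 51% N+; 3% M1; 14%
basaloid histology; 8% 3D-CRT; chemotherapy mixture from the printed
regimen counts (5.8% none, 90.5% mitomycin-based, 1.1%
cisplatin-based, 2.7% other). Tumour volume is log10-normal (sd 0.45
dex) with centre-specific medians chosen so centre mean GTVs span
23.9–120.5 cm³; prescribed dose is a single cohort-wide N(53.2, 4.2²)
Gy EQD2 at 1.8 Gy per fraction (GTV is deliberately the only covariate
with centre-level location shifts; the real study's modest
centre-to-centre dose variation is not emulated because it would
confound the dose effect with centre-level baseline heterogeneity).

Event times follow Weibull proportional-hazards models per endpoint,
`S(t|x,c) = exp(−(t/λ)^k · M_c · e^{β'x})`, with true coefficients set
to the log of the published hazard ratios. Shapes are k = 1.2 (OS,
mildly rising all-cause hazard) and k = 0.9 (LRC/FFDM, early-failure
dominated). The scales λ = 446 / 5131 / 4027 months were calibrated
once so that the *observed* event fractions under the default
censoring design match the published 20% / 15% / 11%, and then frozen.
Centre heterogeneity enters as log-normal baseline multipliers M_c
(sd 0.2 for OS, 0.1 for LRC/FFDM — mortality varies more across
centres than tumour control), drawn fresh per simulated cohort as part
of the design's randomness. Latent times for death, locoregional
failure and distant metastasis are drawn independently given the
covariates and then pushed through the same censoring rules applied to
real records, so the semi-competing structure of the derived endpoints
is exercised rather than bypassed. Administrative censoring comes from
uniform accrual over 90 months truncated 94 months after study start
(median potential follow-up ≈ 49 months); 1% of patients additionally
receive a resection-related censoring time.

What the simulator does *not* emulate: correlation between the three
latent event processes beyond shared covariates and shared centre
frailty; informative censoring; measurement error or coding drift
between centres; non-proportional hazards; and calendar-time treatment
trends. Passing tests therefore demonstrate the correctness of the
computation and the internal consistency of the pipeline under a
well-specified proportional-hazards world — not that the fitted models
would calibrate on real patients.

## Frequentist behaviour at the default size

At n = 1428 with fresh centre multipliers per cohort, simulation shows
the OS model's 95% Wald intervals cover the true log hazard ratios at
rates within [0.90, 0.98] for all eleven coefficients, with absolute
bias below 0.05. Two caveats are intrinsic rather than implementation
artefacts. First, covariates with centre-level structure (notably
log10 GTV) show mild undercoverage (~0.93): centre frailty correlates
by chance with centre-level covariate means in any single cohort,
inflating the sampling variance beyond the model-based standard error.
Second, the ~1%-prevalence cisplatin dummy has only ~3 expected
events; its maximum-likelihood estimate is heavy-tailed, a few percent
of cohorts have no finite maximum at all, and conditioning on
existence induces a selection bias of its own — for the even rarer
event counts of the LRC/FFDM models this finite-sample bias reaches
0.06–0.09 and no amount of implementation care removes it. Simulation
checks therefore assert the recovery bands on the OS model.

## Problem sizes used in the test suite

Equivalence checks run 20 random partitions (2–14 centres) of 10
random datasets with n between 50 and 2000; recovery runs 200
replicate default cohorts; discrimination-stability runs full LOCO on
three replicate cohorts per endpoint; calibration self-consistency
re-simulates one full cohort from its own fitted models (≥ 96
centre-group points). These sizes keep the complete suite under a
minute on one CPU while leaving the Monte-Carlo error of each asserted
quantity well inside its acceptance band.
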