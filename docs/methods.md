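# Methods

This note documents the model, its assumptions, the synthetic evidence
that drives the default analysis, and the numerical choices made where
the design was genuinely open.

## Model structure

A cohort of patients with resected/resectable G/GEJ adenocarcinoma
starts in the event-free survival state (EFS) and can move to first
progression (PD1, second-line treatment), subsequent progression (PD2,
best supportive care) and death. The trace runs on 4-week cycles
(28/30.4375 ≈ 0.92 months) over a 10-year horizon; 10 y × 365.25 d /
28 d = 130.4, truncated to **130 cycles**.

The model is *semi-Markov*: exits from PD1 and PD2 depend on time since
entering the state, not on model time. This is implemented with
entry-cohort ("tunnel") bookkeeping — PD1/PD2 occupancy is stored per
entry cycle, and each entry cohort's transition probabilities are
evaluated on its own residence clock. A cohort entering during cycle *u*
starts its clock at the beginning of cycle *u + 1*. When transition
probabilities are residence-independent the engine reproduces a plain
Markov matrix product exactly (tested), and it agrees with a
200,000-walker individual-level microsimulation within 0.005 occupancy
on a randomized residence-dependent schedule (tested; the
microsimulation exists only as a test oracle).

Per-cycle quantities use **half-cycle correction** (trapezoid of
start-of-cycle occupancies) and are discounted at 3%/year (range 0–5% in
sensitivity analysis) with weights (1.03)^(−t/12) evaluated at cycle
midpoints.

### EFS exit split

Marginal EFS and OS curves do not identify how EFS events divide between
progression and pre-progression death. Default: the death share of each
cycle's EFS exit is min(1, h_OS(t)/h_EFS(t)) from the first-line OS and
EFS fits at the cycle midpoint, the remainder entering PD1. A constant
split is available (`efs_split="constant"`). This is a modelling
assumption, not an estimate.

### Post-progression transitions

PD1 exits combine the second-line OS fit (death) and PFS fit
(progression) on the residence clock: per-cycle death probability comes
from the OS fit, and the PD1→PD2 probability is the PFS event
probability net of deaths, floored at zero. PD2→death reuses the
second-line OS hazard on a fresh residence clock — a deliberate
simplification, since no third-line evidence source is modelled.

## Survival fitting

All families are fitted by maximizing the right-censored log-likelihood
Σ_events log f(t) + Σ_censored log S(t), with parameters on an
unconstrained working scale, multi-start Nelder-Mead plus a BFGS polish
(function tolerance 1e-8). Non-convergence is flagged on the returned
object, never silently dropped.

* Standard families: exponential, Weibull, Gompertz (negative shapes
  allowed), log-normal, log-logistic, gamma, generalized gamma (Stacy).
* Royston-Parmar: restricted cubic spline in log time on the log
  cumulative hazard, log cumulative odds, or probit scale. Default 1
  interior knot at the median log event time, boundary knots at the
  extreme event times; with 0 interior knots the hazard-scale model is
  exactly Weibull (tested to 1e-3 nats). Monotonicity of the cumulative
  hazard is enforced by a quadratic penalty on the spline derivative
  over the knot span.
* Fractional polynomials: FP1/FP2 on the log-cumulative-hazard scale
  with powers from {−2, −1, −0.5, 0, 0.5, 1, 2, 3} (0 → log t; repeated
  powers add a t^p·log t term), selected by deviance, same monotonicity
  penalty.
* Mixture cure: S(t) = π + (1 − π)·S_u(t), logit-parameterized cure
  fraction, Weibull latency by default; a boundary estimate of π is
  reported in the fit message.
* A generalized additive family is registered but raises
  `NotImplementedError`: no parameterization is adopted here.

Model comparison sorts by AIC; the "conservative" selection policy takes,
among converged fits within ΔAIC ≤ 3 of the best, the one with the
lowest extrapolated 10-year survival (ties by BIC then registry order) —
a guard against over-optimistic tails when follow-up is immature. The
base-case family assignments are Weibull (DFLOT EFS), exponential (FLOT
EFS), gamma (second-line OS) and RP-hazard (second-line PFS); first-line
OS uses the same families as its arm's EFS, a parsimonious choice made
here. Per-cycle transition probabilities are p_u = 1 − S(t_{u+1})/S(t_u).

For probabilistic sensitivity analysis the fit parameters are resampled
from a multivariate normal on the working scale using the
finite-difference observed information matrix (eigenvalue-floored);
curve resampling can be frozen by config.

## Synthetic evidence (what it emulates, what it does not)

No patient-level or digitized data from the source trials are publicly
deposited, so the default evidence is simulated at the published scale:

* First-line EFS: 474 subjects/arm; control exponential calibrated to
  the published 2-year landmark 58.5% (λ = −ln 0.585/24 per month);
  treatment arm by proportional hazards with HR 0.71 (implying a 2-year
  landmark ≈ 68.4%, accepted as close to the printed 67.4% since the
  trial effect is not proportional). Administrative censoring at 36
  months.
* First-line OS: each arm exponential calibrated to its own 2-year
  landmark (70.4% / 75.7%), since the OS effect is delayed and a single
  HR would misstate both landmarks.
* Second-line OS/PFS: single-arm Weibull (shape 1.2, 330 subjects,
  24-month censoring) with medians 9.6 / 4.4 months — placeholders in
  the published clinical range for ramucirumab + paclitaxel, **not**
  digitized trial estimates, because the original second-line fits are
  in unavailable supplementary material.

The generator reproduces the statistical structure the pipeline assumes
(exponential/Weibull event processes, uniform-in-interval censoring
within risk intervals, proportional hazards between arms). It does not
reproduce plateauing KM tails, non-proportional treatment effects,
covariate structure, PD-L1 subgroups or surgery rates. Passing tests
therefore demonstrate that the pipeline recovers what it assumes — they
do not validate the published absolute ICER, which additionally depends
on curve shapes that are not printed.

## Kaplan-Meier reconstruction

The reconstruction solves, within each number-at-risk interval, for the
censoring count (assumed uniform over the interval) that makes the
product-limit recursion land on the next published at-risk figure, then
assigns integer event counts to each digitized drop. Digitizer noise is
repaired by running-minimum monotonization and clipping to [0, 1] with a
warning; a coordinate is interpolated at any risk boundary lacking one.
A click at time τ carries the drop accumulated since the previous click,
so the click sitting on a risk boundary closes the preceding interval
and its events are emitted at the midpoint of their bin (keeping the
implied at-risk counts consistent, which makes reconstruction idempotent
on its own KM output). In the final interval, with no closing at-risk
figure, no interior censoring is assumed and survivors are censored at
the last digitized time. Published total event counts, when available,
rescale the inferred counts (largest-remainder rounding); by default no
total is used, as none is printed per arm here.

## Economics

Cycle costs and utilities multiply half-cycle-corrected occupancy and
midpoint discount weights. Conventions, in the order they matter:

* **Treatment calendar**: model cycles 0–1 neoadjuvant (each bundling
  two 2-week FLOT administrations), cycle 2 surgery (gastrectomy
  $1,910.80 charged once to EFS occupancy), cycles 3–4 adjuvant, cycles
  5–14 durvalumab monotherapy (DFLOT only) — 14 durvalumab-bearing
  cycles in total. Treatment receipt is gated by EFS occupancy.
* The parameter table's "drug cost per cycle" rows are read as per
  4-week **model** cycle (the declared cycle length); a per-2-week-chemo
  reading is a config switch. Infusion fees: each FLOT administration
  day one long-infusion fee; durvalumab one short fee; second-line
  cycles two long + one short (days 1/8/15).
* Drug prices are per cycle, so body weight and BSA (kept as sampled
  parameters) do not enter the cost mapping; the Mosteller formula is
  implemented **with** the square root — the printed reference BSA of
  1.99 m² for an 84.7 kg adult is only consistent with the square-root
  form.
* Second-line drugs + administration apply per PD1 cycle; best
  supportive care ($16,632.03) per PD2 cycle by default (per-episode
  switch available); one hospice episode ($4,563.28) per incident death.
  The published best-supportive-care range has min > base (evident
  typo) and is repaired to ±25% with a warning.
* Adverse events (grade ≥3, incidence ≥5%: diarrhea, anemia,
  neutropenia, thrombocytopenia): expected cost Σ p_i·c_i and utility
  decrement Σ p_i·d_i charged once at treatment start, undiscounted,
  with the decrement applied for one cycle.
* Follow-up: CT at months 6, 12, 18, 24, then 36, 48, 60; visits + CBC
  every 3 months to 2 years then 6-monthly, applied to alive non-PD2
  occupancy; the first visit is priced as an initial encounter.
* Utilities: EFS 0.797, PD 0.577; the gastrectomy utility 0.773
  replaces the EFS utility for 13 cycles after surgery.

ICER is reported only when one strategy is costlier and more effective;
dominance and zero-ΔQALY cases are labelled instead of returning a
misleading ratio.

## Sensitivity analyses

OWSA varies each parameter to its published bounds (±25% where no
published range exists; utilities clipped at 1) holding the rest at
base, reporting ICER and incremental-NMB swings — the NMB swing is the
stable statistic when ΔQALY is small. PSA (default 5,000 draws) samples
gamma for costs, beta for probabilities/utilities, normal for
weight/BSA, method-of-moments from mean and range-derived sd =
(max − min)/(2·1.96); parameters are drawn independently (only marginals
are published) and shared across strategies per draw. CEAC and EVPI
follow their definitions on the resulting cloud. The adjuvant-completion
scenario holds the 4 chemotherapy-concurrent durvalumab cycles fixed and
scales monotherapy drug cost by expected cycles = 0.523·10 +
0.477·m, m ∈ {2,4,6,8,10} (the published text rounds the non-completer
share to 48.3%; 0.483 is accepted by config with a warning). Efficacy is
deliberately unchanged — the scenario isolates the cost effect.

## Problem sizes and determinism

Default analyses use 474 subjects/arm (first line), 330 (second line),
130 cycles, 5,000 PSA draws; tests exercise the same code paths at
n = 150–2,000 subjects and 8–60 PSA draws, with the deep oracles
(200,000-walker microsimulation, 2,000-observation parameter recovery
for all seven families) run once each. Every stochastic component takes
an explicit integer seed; identical seeds reproduce byte-identical
outputs, and the full-analysis manifest records SHA-256 checksums of
every artifact.

## Known limitations

* Second-line evidence is an explicit placeholder; absolute cost and
  QALY totals (and hence the ICER) should not be read as estimates of
  the published analysis, whose inputs are not reproducible from print.
* No background general-population mortality (the extrapolated disease
  curves dominate over a 10-year horizon in this population); a hook
  exists but is off by default.
* No covariate-adjusted survival models; arms are fitted separately.
* AE burden is a one-off at treatment start; recurring or late toxicity
  is not modelled.
* Parameter correlation in PSA is not modelled (marginals only).
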