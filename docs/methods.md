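# Methods

## The melodic grammar

A melody is a concatenation of cells, each a first-order Markov chain over
scale degrees 1–7 (degree 7 is degree 1 an octave up). Exposure melodies
use one of two orders, chosen uniformly: start → IC-α → intermediate →
IC-β → end, or start → IC-β → intermediate → IC-α → end. Each IC cell is
exactly two notes, a context and a target one scale degree away:

| cell | context | 0.95 target (low IC) | 0.05 target (high IC) |
|------|---------|----------------------|------------------------|
| IC-α | 3       | 4 (ascending)        | 2 (descending)         |
| IC-β | 5       | 4 (descending)       | 6 (ascending)          |

Global constraints, enforced within cells by the transition tables and at
cell boundaries by restricting each cell's initial distribution to degrees
legal after the entry degree: no immediate repeats, no steps larger than
four scale degrees, and the four reserved pairs (5→4, 5→6, 3→4, 3→2)
confined to IC cells. Boundary dead ends are resolved by resampling the
melody, capped at 100 attempts before a hard error; the cap is never
reached in practice with the shipped tables.

Cell lengths are drawn uniformly from: start 1–3, IC exactly 2,
intermediate 2–4, end 2–3, giving exposure totals of 9–14 notes. The
forced-choice variant drops the intermediate cell and one IC cell (chosen
uniformly) and uses start 2–3 / end 3–4, giving 7–9 notes with the target
at position 3–4 (0-based) — always in the middle third.

### Filler calibration

The filler transition tables are free parameters of the design: the
defining requirement is that, over the whole corpus, the conditional
probability of each reserved pair is the branch probability diluted by the
share of context occurrences that fall outside IC cells, i.e.
`p(4|5) ≈ 0.95 × share(5 in IC-β)`. The shipped tables route enough filler
traffic through degrees 3 and 5 that this share is a bit above one half,
placing the 0.95 branches at ≈ 0.86 bits (band 0.7–1.4) and the 0.05
branches at ≈ 5.1 bits (band 5–6) on a 5,000-melody corpus, while keeping
the overall frequencies of the target degrees 2, 4 and 6 within ≈ 3.7
percentage points of each other (≤ 5 allowed). These bands operationalise
"approximately 1" and "approximately 5–6" bits; they are configurable in
`CalibrationBands`. The tables were tuned once against corpora generated
from development seeds and then frozen; `melgram calibrate` re-measures
any grammar document.

## Pitch mapping and rendering

The hexascale is a six-interval semitone pattern summing to 12 with no
rotational symmetry (default `(1,2,2,1,3,3)`, anchored at MIDI 60). The
tonic condition (0–5) slides a seven-degree window along the repeating
lattice; asymmetry guarantees the six conditions give six distinct
interval profiles, so interval-specific effects average out across
participants. Degree 7 always lands one octave above degree 1.

Rendering writes type-0 standard MIDI: 500 ms inter-onset interval, 450 ms
notes (isochronous by design), program 0, base velocity 80, accent
increment +32 — audible but below the velocity ceiling; the accent
magnitude has no published reference value and is configuration.
Agrammatical variants swap the *pitches* of degrees 5 and 6 at render
time; the degree sequence is untouched, so the swap is an involution.

## Simulated responses

Participants carry a random intercept `u ~ N(0, σ_u²)` shared across their
choices, a musician flag, a grammaticality rating gap δ and rating noise.
Ratings are `round(clamp(4 + u + δ·1[grammatical] + ε, 1, 7))`. Forced
choices are Bernoulli with logit-linear predictors: for accent preference,
`β0 + β_peak·1[peak] + β_IC·1[high] + β_mus·1[musician] +
β_ICxmus·1[high]·1[musician] + u`; for IC preference, the analogous
`γ` set over accent, musicianship and their interaction.

Defaults (n = 78, musician fraction 0.5, β_peak = 0.5, all other choice
effects 0, σ_u = 0.5, δ = 1.5, noise SD 1.0) encode the qualitative ground
truth the analysis is validated against: a real contour effect with null
IC and musicianship effects, and clear grammar learning. The true human
effect sizes are not recoverable from published summary statistics, so
these are scenario parameters, not estimates. The simulator models no
memory decay, attention lapses, response times, order effects or liking
drift (a linear drift hook exists but feeds no analysis); passing
parameter-recovery tests therefore shows the *statistical pipeline* is
correct under the assumed response model, not that human listeners behave
this way.

By default `simulate_cohort` builds, per participant, only the
response-bearing phases (learning test and the two forced-choice tests);
the exposure phase collects no analysable responses. The full protocol
builder can be supplied explicitly when schedule-level structure matters.

## Mixed models

Both forced-choice analyses are binomial GLMMs with a scalar participant
intercept, fit by marginal maximum likelihood: each participant's
Bernoulli product is integrated over `u` with 25-node Gauss–Hermite
quadrature (accurate for a one-dimensional random effect) and the
marginal log-likelihood is maximised with L-BFGS-B over `(β, σ_u)` with
`σ_u ≥ 0`, warm-started at the pooled logistic solution. Standard errors
are Wald, from a central-difference Hessian at the optimum; when `σ_u`
sits on the zero boundary its row is dropped (the Wald approximation is
invalid there) and the fixed effects then coincide with pooled logistic
regression. BIC is `-2·loglik + k·log(N)` with `k` counting fixed effects
plus the variance and `N` the number of observations, matching lme4's
convention; the implementation agrees with `lme4::glmer` (nAGQ = 25) to
~1e-3 on coefficients, log-likelihood and BIC in the test suite.
Non-convergence (optimizer failure or an indefinite Hessian) flags the fit
and warns; it is never silent.

Contour enters the accent model as a four-level treatment-coded factor
with *descending* as the reference level (a free choice; no reference
level is canonical here). The per-participant `Δ_peak` statistic collapses
contour to peak vs non-peak, deliberately coexisting with the four-level
factor. Nested models for the likelihood-ratio test drop whole conceptual
terms (dropping IC also drops the IC × musicianship interaction, df = 2;
dropping the contour factor costs df = 3). No multiple-testing correction
is applied. Participants with an empty stratum are excluded listwise from
the affected t-test, with counts reported.

## Problem sizes and numerical choices

Calibration checks use 5,000-melody corpora (IC standard error ≈ 0.1 bit
for the rare branches); branch-rate checks use 10,000 cell samples (3
binomial SE ≈ 0.0065); parameter recovery uses 40 replicate cohorts of
n = 78 and requires the generating pattern in ≥ 90% of them; the null
type-I-error check uses 200 small cohorts against a 3-SE band around
α = 0.05. Monte-Carlo assertions throughout use 3–4 SE bands rather than
significance thresholds so that a correctly null effect does not fail a
seeded test at the nominal rate.

## Known limitations

* Only first-order grammars; no variable-order or long/short-term mixture
  surprisal models.
* No audio beyond MIDI (no mp3, loudness normalisation or microtonality).
* Rhythm is fixed: isochronous, equal durations; metrical structure is
  varied only through cell-length jitter.
* The response model is intentionally minimal (no drift, lapses or
  response times), so recovery results validate the analysis, not
  human behaviour.
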