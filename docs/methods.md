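# Methods

## Belief states

A polar question induces a binary issue. A listener's first-order belief
is the probability vector **p** = ⟨p, 1−p⟩ over the 'yes'/'no' answers;
after hearing the answer it becomes **q** = ⟨q, 1−q⟩. Second-order
belief — uncertainty about p itself — is modelled as a unimodal beta
density over [0, 1], requiring α, β > 1. We use the mode/concentration
parameterization

    ω = (α − 1) / (α + β − 2),    κ = α + β,

inverted as α = 1 + ω(κ−2), β = 1 + (1−ω)(κ−2), because it maps directly
onto what is measured: the mode ω is identified with the reported point
probability, and the concentration with the 7-point commitment rating
through the linking function κ = a·bᶜ (a > 0, b > 1 free parameters,
fitted). An exponential link is used because commitment scales tend to
compress large evidence differences; the choice is an assumption of the
package, fitted per measure.

Numerical guards: probabilities entering log/odds computations are
clamped to [1e-6, 1 − 1e-6]; modes are clamped to [1e-4, 1 − 1e-4] before
shape inversion; linked concentrations are floored at 2.01 to preserve
unimodality. Because commitments are bounded by 7, the link itself caps
κ at a·b⁷ — the practical upper bound on concentration. These guards
never override an explicitly defined boundary value: Bayes factor
utility is defined as 1 when p or q is exactly 0 or 1 with p ≠ q, and KL
utility is defined as 1 when the prior is degenerate and differs from the
posterior (the limit of g as the divergence diverges). When prior equals
posterior, the no-change convention (value 0) takes precedence over the
boundary rule. All logarithms are natural; since the scale base r of
g(x) = 1 − r⁻ˣ is fitted, the base convention is absorbed by
reparameterization.

## The measures

Nine measures live in a fixed registry (see README for the table). Two
definitional points deserve a note:

* **Bayes factor utility** is implemented as 1 − min(BF, 1/BF) with
  BF = [q/(1−q)]·[(1−p)/p]. This is the simplification of g(|log BF|)
  when the scale base equals the log base, which makes the measure
  parameter-free, confined to [0, 1], zero iff p = q, and symmetric
  under swapping prior and posterior.
* **Second-order Bayes factor utility** is g(log(|Δα| + |Δβ| + 1)); the
  inner quantity counts the pseudo-observations separating posterior
  from prior shapes and equals 1 (so the measure equals 0) on a null
  update. A printed variant of the form 1 − g(·) circulates; it assigns
  utility 1 to a null update, violating the convention every other
  measure obeys, so it is available only behind the explicit
  `table_literal=True` keyword for comparison.

**Commitment change** is reported raw on 0..6. For fitting and
prediction it is multiplied by a proportionality coefficient estimated
by least squares (closed form), so its MSE is commensurable with the
unit-interval relevance slider; correlation- and rank-based comparisons
are scale-free and use the raw values unchanged.

The **generalized Bayes factor utility** for n-alternative questions is
the posterior-weighted average Σᵢ qᵢ·BFU(pᵢ, qᵢ). It reduces exactly to
the polar form at n = 2 and equals 1 whenever prior or posterior puts
all mass on one alternative (except when prior and posterior have
disjoint supports, a pathological case).

Differential entropy and KL divergence of beta beliefs use the k = 2
Dirichlet closed forms (betaln/gammaln/digamma); both are verified
against adaptive quadrature to 1e-6 over a shape grid in the test suite.
The KL closed form returns exactly 0 when the two parameter pairs are
identical (intermediate rounding otherwise leaves ~1e-16).

## Synthetic experiments

The generator emulates the trial structure of a within-subjects
relevance study: each participant completes 14 trials in a fixed
sequence (10 main, 2 attention checks, 2 reasoning checks). Main trials
cross ContextType (negative/neutral/positive prior bias), AnswerCertainty
(exhaustive / high-certainty / low-certainty / non-answer) and
AnswerPolarity (positive/negative; non-answers are always coded
positive), under per-participant quotas: ≥2 exhaustive, ≥2
high-certainty, ≥2 low-certainty, ≥1 non-answer; ≥1 of each polarity
within every informative certainty level; ≥3 of each context; 10
vignettes drawn without replacement from 12.

The participant model works in log-odds space:

* the prior p is drawn from a context-dependent beta distribution with
  mean 0.30 / 0.50 / 0.70 (negative / neutral / positive) and
  concentration 12, plus slider noise (sd 0.03), rounded to the slider's
  2-decimal granularity;
* the answer carries evidence of ±0.8 (low-certainty), ±2.0
  (high-certainty), or ±∞ (exhaustive, capped at q ∈ {0.01, 0.99};
  `exact_boundaries=True` allows exact 0/1) log-odds, signed by
  polarity; the posterior log-odds are prior log-odds plus
  trust × evidence, with trust drawn per participant from U(0.75, 1);
* commitments are a monotone map of distance-from-½ (c ≈ 2 + 8·|p−½|),
  the posterior commitment additionally bumped by evidence strength,
  jittered (sd 0.5) and clipped to 1..7;
* relevance is the value of a chosen generating measure on the trial's
  beliefs (at the measure's default parameters) plus truncated-Gaussian
  noise (sd 0.05 by default; 0 gives the measure value exactly).

Default measure parameters — the generating truth — are the study-scale
best-fit values: r = 1154.73 (entropy change), r = 885603.86 (KL
utility), (a, b, r) = (1.49, 1.52, 1.19), (2.00, 2.01, 2.18),
(2.09, 1.89, 2.73), (3.20, 5.19, 1.14) for concentration change and the
second-order entropy/KL/Bayes-factor measures respectively. The default
sample size is 220 participants (the analyzed-sample scale); tests and
examples use 15–200 to keep runtimes in seconds to tens of seconds.

What the generator does **not** emulate: non-epistemic contributions to
relevance (speaker credibility, askers' broader goals or preferences),
vignette-specific content effects, response-order effects, and
ordered-beta response distributions (a truncated Gaussian is the
default; clipping at 0/1 produces boundary inflation but not the full
ordered-beta shape). Passing tests therefore show that the *machinery* —
measures, fitting, comparison — behaves correctly and is unbiased across
generating measures, not that any particular measure fits human data.

Attention checks instruct fixed (probability, commitment) pairs —
(0.30, 6) and (0.80, 2), constants of the generator config; a compliant
judgment reproduces them exactly. Reasoning checks are abstract
pass/fail events per judgment (the underlying scenarios are not
modelled); correctness flags travel in `truth_*` columns.

## Exclusion filters

Applied sequentially so no participant is double-counted:
(i) any imperfect attention judgment (slider compared at 2-decimal
granularity, commitment exactly); (ii) reasoning score strictly below
50% over the eight reasoning judgments — the relevance-only mode relaxes
this to "both trials wrong"; (iii) task sensitivity ≤ 0.75, where a main
trial (non-answers excluded) is sensitive if |p − q| > 0.05 or the
commitment changed. The sensitivity wording is ambiguous in circulating
descriptions (the clause literally describes *insensitive* trials); we
adopt the reading where higher sensitivity means more responsive, which
matches the exclusion direction. The probability delta is rounded to
9 decimals first so a slider move of exactly 0.05 counts as "0.05 or
less" (insensitive).

## Fitting

Each measure is fitted independently by minimizing the mean squared
error against relevance over all main trials (including non-answers).
Search: a logarithmic grid over r ∈ [1.001, 1e7], a ∈ [0.1, 20],
b ∈ (1.01, 20], followed by Nelder-Mead refinement on log-parameters
from the best few grid points (the 3-parameter second-order objectives
have shallow local basins; multi-start refinement is cheap and
deterministic). Parameters are box-clamped to the searched region during
refinement. (a, b, r) can trade off, so recovery is guaranteed — and
tested — in prediction space: refitting on noiseless self-generated data
reaches per-trial MSE < 1e-6 for all nine measures.

`compare_joint_linking` quantifies the cost of forcing one shared
linking function across the second-order measures (shared (a, b),
per-measure r), reporting each measure's MSE penalty relative to its
individual optimum.

## Evaluation

The headline comparison uses two desk-computable, scale-free criteria:
per-trial MSE and an item-level Pearson correlation, where an item is
one answer-in-context cell (vignette × certainty × polarity × context)
and judgments are averaged over participants. This deliberately
substitutes for hierarchical ordinal regression with cross-validated
model comparison: those models are off-the-shelf machinery, whereas the
measures and the item-level analysis are what this package contributes.
Item-mean commitments stay real-valued (the linking function accepts
real exponents). A two-dataset mode pairs beliefs from one experiment
with relevance means from another sharing the same items (the
relevance-only protocol).

Rankings break ties by registry order; rank agreement is Spearman's ρ;
per-trial rank differences use average ranks, so they sum to zero.
Ordinal design checks compare group means with seeded bootstrap
percentile intervals (1,000 resamples by default).

## Problem sizes and determinism

Test-suite and example runs use 15–120 participants; the identifiability
and design-reproduction checks use 200 participants with noise sd 0.05
and fixed seeds, at which scale the generating measure reliably ranks
first on both criteria for both tested generators. All randomness flows
through a single `numpy` Generator seeded at the entry point; identical
config + seed reproduces datasets, fits and reports byte-identically.

## Known limitations

* Second-order beliefs are restricted to unimodal beta distributions;
  mixtures or multimodal states are out of scope.
* The certain second-order prior (a point mass) is not representable as
  a beta distribution; the concentration cap stands in for it.
* The MSE objective weights all trials equally; no participant- or
  item-level random effects are modelled.
* The generalized Bayes factor utility is implemented and tested against
  its analytic properties but not against behavioral data.
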