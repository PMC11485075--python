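# Methods

## The processing-tree model of word-list recall

The package models one word's episodic trace during a 10-word list
test with three presentation + immediate-free-recall (IFR) cycles and a
final delayed free recall (DFR) with no re-presentation. The trace
occupies one of three states — pre-task storage **p** (semantic only,
cannot emit recall), transient storage **T** (supports IFR only) and
durable storage **D** (supports IFR and DFR) — and the task schedule is

    [present, recall-IFR] × 3, then [recall-DFR].

At a presentation, a word still in p is encoded one-shot into D with
probability *N*₁, otherwise transiently into T with probability *N*₂
(nested branches: P→D = *N*₁, P→T = (1−*N*₁)*N*₂). A word already in T
is consolidated into D with probability *N*₃; D is absorbing. At an IFR
recall attempt, T emits with probability *R*₁ and D with *R*₂; at DFR
only D emits (with *R*₃) — transient storage supports immediate recall
only, so whether T persists through the delay is irrelevant. After a
successful recall from T, the testing effect moves the trace to D with
probability *N*₄.

Choices the model's verbal description leaves open, and how this
implementation resolves them:

* **Branch order from p.** The one-shot branch *N*₁ is taken before the
  transient branch *N*₂ (standard nested MPT convention). The
  convention is isolated in `advance_presentation`; the rest of the
  code is agnostic to it.
* ***N*₃ timing.** Consolidation applies at every presentation to words
  already in T. Since T is unoccupied at the first presentation this is
  equivalent to "from task 2 onward", and it never applies at DFR
  because no presentation precedes the delayed task.
* **No re-encoding from T.** A word in T at a re-presentation does not
  receive a fresh *N*₁/*N*₂ draw; those parameters remain interpretable
  as encodings from pre-task storage.
* **Position effects** act additively on the logits of *N*₁ and *N*₂ at
  the corresponding presentation only (one offset per list × position;
  default zero). Degenerate probabilities 0 and 1 are fixed points of
  the adjustment.

The likelihood of an observed 4-slot pattern is computed by a forward
recursion over the 3-state space in linear probability space
(products over words accumulate in log space inside the sampler). The
suite pins the recursion against an independently written brute-force
path enumeration to 1e-12, and the 16 pattern probabilities sum to 1 to
the same tolerance.

## Recall-ability scores

*M*₁ and *M*₂ are the marginal probabilities that a word is recalled on
an IFR task through T and through D respectively, averaged over the
three IFR tasks at zero position offset; *M*₃ is the marginal DFR
recall probability. The marginal state occupancies needed for these
integrate over recall outcomes, so the testing effect contributes a
T→D flow of *R*₁*N*₄ per IFR task. *N*, *R* and *M* are plain averages
of their components. The definitions are pinned by a route-bookkeeping
simulation test (2×10⁵ simulated words; agreement within 3 Monte-Carlo
standard errors).

A structural consequence worth knowing: because each *M*ᵢ is a
retrieval probability weighted by a state occupancy, *M*ᵢ ≤ *R*ᵢ always,
hence *M* ≤ *R*, and since the three IFR occupancies partition across T
and D, *M*₁+*M*₂ ≤ 1 and therefore *M* ≤ 2/3. Published cohort-level
*M* values computed with proprietary recombinations of the same seven
parameters can exceed these bounds; such values are not attainable
under the route-attributed definition used here, and the synthetic
generator is calibrated accordingly (below).

## Inference

Each participant's seven probabilities are updated independently
against fixed demographic-group priors (the alternative — one joint
hierarchical fit across participants — is a possible extension). The
sampler is adaptive component-wise random-walk Metropolis on
logit-transformed parameters: 4 chains × 2,000 iterations with 1,000
burn-in by default, proposal scales adapted during burn-in toward an
acceptance rate of 0.234 (a deliberately conservative target; 0.44 is
the component-wise optimum and both are configurable). Priors are
independent Beta(α, β) per parameter; on the logit scale the density
picks up the Jacobian p(1−p), making the exponents exactly α and β.

Derived *M* scores are computed per retained draw and summarized
alongside the parameters (posterior mean, SD, central 95% credible
interval, bulk ESS and split-chain R-hat via ArviZ; participants with
any R-hat > 1.05 are flagged).

Randomness is keyed per (participant, chain) from the master seed plus
a stable hash of the participant's data and prior, so results are
byte-identical across runs, independent of batch composition, and
identical participants yield identical summaries.

Demographic groups are age (<65, 65–75, >75) × sex × education (<16,
≥16 years) — 12 strata plus an explicit default. When no prior file is
supplied, `estimate_group_priors` provides an empirical-Bayes
substitute: every calibration participant is fit under flat Beta(1, 1)
priors, and a Beta is moment-matched per group and parameter to the
spread of posterior means (α, β clipped to [0.5, 500]; groups with
fewer than two members merge into the default group). This replaces
proprietary population priors and is documented as such.

## Traditional scores

The immediate score is the mean count of words *not* recalled over the
three IFR tasks, the delayed score the count not recalled at DFR. Both
are error scores (higher = worse); the package never flips their
polarity, so in regressions their coefficients have the opposite sign
to the biomarkers'.

## Synthetic cohort generator

The generator emulates the structure of a 330-participant memory-aging
cohort: age ~ N(71.4, 7.2²), 184/330 male, education ~ N(16.3, 2.6²)
rounded to years, PHS ~ N(0.339, 0.779²), baseline CDR drawn from
{0, 0.5, 1} with probabilities 29/330, 300/330, 1/330. True parameters
are drawn per participant from independent logit-normal distributions
with base probabilities (0.56, 0.62, 0.52, 0.04, 0.85, 0.95, 0.95),
logit SD 1.28 and an age trend of −0.015 logits/year. These values were
calibrated once so the cohort mean of *N* is ≈ 0.431 and *M* has mean
≈ 0.534 with SD ≈ 0.083; given the *M* ≤ 2/3 bound above, the generator
targets this feasible operating point rather than cohort *M* means
quoted for proprietary recombinations, and *R* (≈ 0.87 here) is left
free.

Decline (CDR increase ≥ 0.5 by 36 months) follows a logistic model
with slope −14.94 on true *M*, a weak PHS effect (slope 0.3), and an
intercept solved at generation time so the expected decliner fraction
is 61/330. Decliners move up {0.5, 1, 1.5} CDR steps with probabilities
(0.64, 0.30, 0.06) capped at 3; non-decliners stay, or revert 0.5 → 0
with probability 0.13 (mimicking observed follow-up improvements).
Recall data are simulated word-by-word from the exact model with
per-task permuted presentation orders.

What the generator does **not** emulate: intrusions, repetitions and
recall order; correlations between the seven parameters (a shared
ability factor is supported via `dcb_shared_sd` but off by default,
because the independent-Beta priors used in fitting would be
misspecified for it); genotype-level PHS structure; real CDR
transition dynamics beyond the printed marginal counts. Passing
recovery tests therefore demonstrates internal consistency of model,
sampler and pipeline under the stated conditions — not performance on
real clinical data.

## Analysis pipeline

* Linear regression (OLS) of CDR at 36 months on a chosen predictor
  subset plus education, sex, PHS, age and baseline CDR, with an
  optional square-root outcome transform; rank-deficient designs are
  rejected with the offending columns named.
* Proportional-odds (cumulative logit) regression over the ordered CDR
  stages, reporting Wald statistics, the likelihood-ratio chi-square
  against the thresholds-only null, and Nagelkerke pseudo-R²; stages
  absent from the data are collapsed with a warning.
* Logistic regression of the decline indicator (baseline CDR excluded —
  it is part of the change score), reporting unstandardized and per-SD
  standardized coefficients and AIC with/without each focal predictor.
  Suspected separation (non-convergence or runaway coefficients)
  triggers a ridge-penalized refit and a warning.
* Screening classification calls decline iff *M* < threshold (strict
  inequality; default 0.58, with a Youden-optimal selector provided as
  a utility since the provenance of any fixed threshold is external to
  the package). Metrics with zero denominators are reported as
  explicitly undefined, never NaN. AUC uses the midrank statistic with
  ties handled by midranks, which equals trapezoidal integration of the
  empirical ROC curve; model ranking uses AIC/BIC rather than Bayes
  factors.

## Problem sizes and numerical choices

Analytic identities are tested at 1e-12. Monte-Carlo pins use 5×10⁴
(pattern frequencies, chi-square p > 0.001) and 2×10⁵ draws (route
attribution, 3 SE). The recovery experiment uses 200 participants × 10
words with 4×2,000 MCMC iterations; the pipeline experiment uses
replicate 330-participant cohorts with 2×1,500 iterations, sizes chosen
to keep full runs in the minutes range on a single core while leaving
Monte-Carlo error well inside the asserted margins. Complete-case
analysis is used throughout, with dropped-record counts logged.

## Known limitations

* The exact branch recombination behind published *M* values is
  proprietary; this package's route-attributed definition is a
  documented, test-pinned substitute, and absolute *M* levels are not
  comparable across the two.
* Participants are fit independently against group priors; no
  information is shared across participants within a fit beyond the
  prior itself.
* Position-effect offsets are fixed inputs, not estimated jointly.
* The proportional-odds fit can be fragile when outcome categories are
  nearly empty; collapsed categories change the threshold
  parameterization.
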