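# Methods

This note documents the generative model, the task simulation, the fitting
and inference procedures, the defaults and the numerical choices, in the
package's own terms. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Generative observer model

The response to the central target is a divisive normalization:

    R(θ) = A_C·C_C / (A_C·C_C + C_S·e^(−θ/w_obs) + σ)

- `C_C = C_S = 0.8`: center and surround drive, matching the 80%-contrast
  stimuli (both gratings have equal physical contrast; the suppression is
  carried entirely by orientation and gain-control terms).
- `A_C` (dimensionless, > 0): amplification of the center following
  segmentation. Segmentation succeeds with focal attention and sufficient
  acuity; default mapping `A_C = 2.0` for logMAR ≤ 0.1 (Snellen 20/25 or
  better), `1.0` otherwise.
- `σ` (> 0): semi-saturation constant = untuned (orientation-insensitive)
  gain control. Group defaults: 0.4 for HC and PBDrel; 0.25 for PBD and
  PSZrel ("intermediate deficits"); for PSZ, 0.1 in the low-acuity
  sub-group (logMAR > 0.1) and 0.4 otherwise. The acuity-conditional PSZ
  rule expresses the hypothesis that weakened gain control is expressed in
  the low-acuity sub-group, which is what the moderation analysis probes.
- `w_obs = 30°`: orientation tuning width of surround suppression, fixed
  across observers (group differences in width are deliberately absent from
  the generator; the tuning-width analyses should find nothing).

### Perceived-contrast read-out

The matched contrast decrement (percentage points, negative = suppression)
for a surround condition is a **linear read-out of R on a scale common to
all observers**, anchored at the canonical no-surround operating point
R₀ = 0.8 (the no-surround response of the baseline A_C = 2, σ = 0.4
observer):

    δ(θ) = (80 / R₀) · (R(θ) − R₀) = 100·R(θ) − 80.

Rationale: the normalized response R is taken to predict perceived contrast,
and model variants are compared on the R scale. A read-out that re-normalizes
each observer by their *own* no-surround response was considered and
rejected: within-observer normalization algebraically inverts the σ effect
(δ(90°) = −80·C_S′/(A_C·C_C + C_S′ + σ), so weaker gain control would
predict *more* matched suppression), contradicting the phenomenon being
modeled — weakened untuned gain control presenting as *less negative*
orthogonal-surround decrements. With the common-scale read-out, weak-σ
observers can show small positive decrements at 90°, which is exactly the
"less negative offset" signature the group analysis targets.

Two consequences are worth noting. First, for the baseline observer the
common-scale and self-normalized read-outs coincide exactly
(80·(R/0.8 − 1) = 100·R − 80), so baseline predictions (−22.86 pp at θ = 0°,
−1.56 pp at 90°) are identical under either convention. Second, conditions
whose effective surround drive is zero (the no-surround condition, or far
surrounds with `far_gain = 0`) present physically identical stimuli on both
sides of the screen, so their PSE is exactly 0 regardless of the observer's
internal parameters; the read-out therefore has a deliberate discontinuity
at zero surround drive (stimulus symmetry overrides the model there).

### Far surrounds

Far-surround conditions multiply `C_S` by `far_gain` (default 0.15): far
suppression is simulated as weak and is analyzed descriptively only, since
the phenomenon of interest is carried by the near surround.

### Decision model

P(report reference higher) = lapse/2 + (1 − lapse)·F(x; PSE, β), with F the
logistic CDF, x the reference decrement, β the decision slope (default 0.5
per percentage point) and lapse the total stimulus-independent error rate
(default 0.04). This is the same family the staircase assumes internally, so
staircase consistency is directly testable; the staircase's slightly larger
lapse setting (δ = 0.08 total) introduces a small, quantified bias (< 0.1 pp
at 48 trials for the default observer).

### Cohort defaults

Group sizes 31/29/29/28/21 (PSZ/PBD/HC/PSZrel/PBDrel). Acuity is sampled
per group from a normal truncated below at logMAR −0.3, with means (sd)
0.14 (0.15), 0.12 (0.12), 0.08 (0.13), 0.10 (0.12), 0.04 (0.10)
respectively — the study-population demographics. Per-observer seeds are
drawn from the cohort stream; every downstream stochastic element (staircase
responses, catch responses, trial shuffle) descends from the observer seed
via fixed spawn keys, which makes session outcomes independent of the trial
schedule and lets the vectorized cohort runner reproduce per-observer runs
bit-for-bit.

## Psi staircase

Grid posterior over threshold α (−40…20, step 1) and slope β (0.1…5, step
0.05), uniform prior (the task defines ranges and precisions only; a uniform
prior is the least-informative choice on the stated grid). Stimulus
placement minimizes expected posterior entropy over candidate reference
decrements (−75…15, step 1), computed through the mutual-information
identity E[H_post](x) = H(prior) − h(p(r|x)) + Σⱼ pⱼ·h(Lₓⱼ) (h = binary
entropy, natural log, 0·log 0 ≡ 0) — two matrix-vector products per trial,
algebraically identical to averaging the entropies of the two candidate
posteriors and verified against a brute-force enumeration oracle. Ties break
toward the smallest intensity, with a tiny (1e−12) absolute tolerance so
exact symmetric ties resolve identically regardless of floating-point
summation order. The per-trial threshold estimate is the posterior mean of α
(not the MAP); the psychometric family is logistic (a cumulative-normal
option is exposed). Total lapse δ = 0.08 is split half per asymptote.

## Session engine

48 staircase trials per condition × 11 conditions + 48 catch trials = 576
trials, interleaved by a uniform random shuffle (only mixing is specified by
the task; the schedule is irrelevant to the staircases because each
condition owns an independent posterior and response stream — an invariant
the tests assert). Catch trials fix the reference at 30% contrast
(decrement −50), split 24 parallel / 24 orthogonal with random near/far
assignment, and never touch a posterior. Rest breaks have no computational
consequence and are not modeled.

Inclusion requires catch accuracy strictly above 0.75 **and** strictly
negative near-surround estimates at 0° and 20° (the operationalization of
"reduced perceived contrast"; participants who attend to the whole pattern
rather than the target show the opposite sign). Catch accuracy is checked
first when recording the exclusion reason. Outliers are flagged per
condition at 5 SD from the condition mean over included observers and are
dropped only from analyses that use that condition as a dependent variable;
because the tuning fit's dependent variables are the five near conditions,
an observer with any near-condition flag is excluded from the parameter
analyses.

## Tuning fit

`scipy.optimize.curve_fit` (trust-region reflective, xtol 1e−8) on
P(θ) = −M·e^(−θ/w) + o with initialization M₀ = P(θ_max) − P(0), w₀ = 30,
o₀ = P(θ_max); w bounded to [1, 180], M and o unbounded; a 5-point w₀
multistart {10, 20, 30, 45, 60} is attempted only if the first start fails,
and an unconverged fit is flagged (and counted inadequate), never raised.
Adequacy is the strict variance-reduction rule var(P − fit) < var(P) with
the population (divide-by-n) convention; constant data are therefore always
inadequate (0 < 0 is false) — a deliberate degenerate-case behavior the
tests pin down. Sign convention: P is the (negative) matched decrement, so
suppression at parallel implies M > 0; group contrasts on M are invariant to
flipping this convention. A caveat the tests also pin down: the
normalization-model curve decays slightly slower than a single exponential,
so on model-generated (noiseless) data the fitted asymptote `o` overshoots
the 90° decrement by ~2.6 pp; `w` is weakly identified from five points
(median absolute recovery error ~11° at noise sd 2), consistent with
tuning-width analyses being null.

## Group statistics

- **Split-plot rmANCOVA** (three conditions: no-surround, near-0°, near-90°;
  between-subjects group; logMAR covariate): between-subjects effects are
  tested on subject means; within-subject effects on orthonormal (normalized
  Helmert) contrast scores with effect-coded group and the centered
  covariate entered per contrast (i.e. a covariate × condition term is
  included, the convention of standard statistical packages; a toggle
  removes it). Type-III sums of squares by model comparison. Huynh–Feldt ε
  is computed from the pooled covariance of the within-model residuals
  (Greenhouse–Geisser ε from orthonormal-contrast covariance, then the HF
  adjustment ((n−g+1)(k−1)ε̂ − 2)/((k−1)(n−g−(k−1)ε̂)), clipped to
  [1/(k−1), 1]) and multiplies the within-effect degrees of freedom.
  F statistics match pingouin's mixed ANOVA exactly in the no-covariate
  case; no installed package offers the covariate-adjusted mixed design,
  which is why the decomposition is implemented directly.
- **One-way ANCOVAs** on M, w, o (statsmodels OLS model comparison),
  reported with and without the acuity covariate; partial η² =
  SS_effect/(SS_effect + SS_error).
- **Moderation**: group + centered logMAR + group × logMAR; F on the
  interaction block with g − 1 numerator df, plus a descriptive split of
  each group at logMAR 0.1.
- **Pairwise contrasts** on covariate-adjusted group means with
  Benjamini–Hochberg FDR (BH, not BY; plain FDR correction is the intended
  procedure).
- **Bayes factors**: a BIC-difference approximation is provided for
  convenience and is explicitly not comparable to JZS/anovaBF values; the
  original headline Bayes factors are out of scope.

Type-I calibration of all three inferential procedures is verified on 1,000
generative-null cohorts (rejection rates within [0.035, 0.065] at α = 0.05).

## What the synthetic cohorts do and do not show

The generator reproduces the study's *structure* (group sizes, acuity
distributions, task and staircase parameters, trial counts) and its
*hypothesized mechanism* (acuity-gated segmentation interacting with
group-dependent untuned gain control). Passing tests therefore show that the
pipeline recovers parameters and group orderings when the mechanism is true
and observers are otherwise well-behaved. They do not show anything about
mechanisms the generator omits: real attentional lapses correlated in time,
response bias, learning or fatigue across the session, eye movements,
optical blur acting on the stimulus itself (acuity enters only through A_C
and the PSZ σ rule), or model misspecification of the psychometric family.
Exclusion and inadequate-fit rates in synthetic cohorts are consequently
near zero, unlike in human data; the bookkeeping for those filters is
exercised by construction, not by realistic incidence.

## Problem sizes and determinism

Default end-to-end problem sizes: 138 observers × 576 trials per cohort
(~10 s on one CPU); 50 replicate cohorts for the detection/ordering rates in
the acceptance script (30 in the test suite, same thresholds); 1,000 null
cohorts for calibration; 200 synthetic participants for fit recovery; 100
staircase replicates for convergence. A fixed master seed makes every
artifact (including manifest content hashes) bit-reproducible; all child
seeds derive from `numpy.random.SeedSequence` spawn keys and stay below
2³¹.
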