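# Methods

`spikemux` asks, for each visually responsive unit recorded while two
stimuli are shown together, whether its combined-stimulus spike counts are
better explained by a fixed response (at one of the single-stimulus rates,
between them, or outside their range) or by trial-to-trial *multiplexing* —
switching between the two single-stimulus response distributions — and then
asks how such switching is coordinated across a simultaneously recorded
population.

## Spike counting and presentation screening

Spikes are counted in a fixed 200 ms window offset by the area's typical
response latency: 30–230 ms after stimulus onset for V1, 50–250 ms for V4.
The window is half-open (`start <= t < end`) so abutting windows cannot
double-count a spike.  Presentations enter the analysis only if the trial
was performed correctly, attention was directed away from the recorded
receptive fields, gaze stayed within a ±0.5° fixation window, and no
microsaccade occurred during the presentation.

Microsaccades are detected as excursions of smoothed gaze speed above
`mean + 6 SD` of the steady-fixation speed.  Conventions the detection rule
itself leaves open were fixed as follows: velocity is the central finite
difference of position in deg/s, smoothed with a 5-sample moving average;
an event needs only one supra-threshold sample; and when no external
baseline is supplied it is estimated in two passes, the first *robust*
(median + 6 × 1.4826·MAD) so that the saccades themselves cannot inflate
the baseline SD — with a plain mean/SD first pass a 0.3° event raises the
threshold above its own peak and recall collapses.  On synthetic traces
with slow ocular drift (~1 deg/s) and injected 0.3° steps the detector's
recall is 1.00 with ≤0.01 false events per presentation.  These choices are
not claimed to match any particular published detector.

## Triplet screening

The atomic analysis unit is the *triplet*: one unit's counts from A-alone,
B-alone, and AB presentations of one stimulus pairing (each condition needs
at least 5 presentations).  Two exclusions protect the downstream model
comparison, which assumes Poisson single-stimulus responses with separated
rates:

1. **Poisson goodness of fit** on each single-stimulus sample: a chi-square
   statistic on integer bins (right tail pooled until the pooled expected
   count is ≥ 1) with a Monte-Carlo p-value — the rate is refit per
   simulated replicate (parametric bootstrap), and the add-one rule
   `p = (1 + #{X²_sim ≥ X²_obs})/(n_mc + 1)` keeps p positive.  Samples are
   retained when `p > 0.10`; on truly Poisson samples of 21 trials the
   exclusion rate is ~0.10 across the rate range 2–40, and negative-binomial
   samples with variance 3× the mean are excluded >80% of the time.
2. **Rate separation**: the arithmetic intrinsic Bayes factor of
   `λ_A ≠ λ_B` against `λ_A = λ_B` under Jeffreys priors must exceed 3.
   Minimal training samples are one observation per condition; all `n_A·n_B`
   pairs are averaged (capped at 200 random pairs), and every marginal has a
   gamma-function closed form.  A fractional Bayes factor (training fraction
   equal to two observations) is available as a cross-check.  The averaging
   scheme is one of several defensible intrinsic-BF constructions; the
   choice matters little here because screened triplets must clear the
   threshold by construction of the separation requirement.

## The four-hypothesis model comparison

Let the single-stimulus counts be Poisson with rates λ_A, λ_B, and let
y₁…y_m be the AB counts.  The four hypotheses for the AB distribution are

* **single** — `Poi(λ_AB)` with `λ_AB ∈ {λ_A, λ_B}` (the two sub-models are
  averaged 50/50);
* **outside** — `Poi(λ_AB)` with λ_AB outside `(min, max)` of the two rates;
* **intermediate** — `Poi(λ_AB)` with λ_AB strictly inside that interval;
* **mixture** — `α·Poi(λ_A) + (1−α)·Poi(λ_B)` with `α ~ Uniform[0,1]`,
  i.e. presentation-by-presentation switching.

Posterior model probabilities use equal ¼ priors; the winner is reported
with its winning probability, flagged at ≥ 0.67 (winner at least twice as
likely as the best alternative) and > 0.5 (at least as likely as all
alternatives combined).

Jeffreys' improper prior λ^(−1/2) is made proper by conditioning on the
single-stimulus data: λ_A and λ_B carry their conjugate
`Gamma(S + 1/2, n)` posteriors, and the free rate of the
outside/intermediate hypotheses carries a Jeffreys density truncated and
renormalised on the hypothesis region.  The outside region is unbounded, so
it is capped at `upper_factor × max(λ_A, λ_B)` (default 10); the winning
probability moves by far less than 0.5 when the cap doubles, and this
sensitivity is exposed as a diagnostic.

### Numerical evaluation

* The **single** marginal is the exact negative-binomial predictive.
* For **outside/intermediate**, the inner integral over λ_AB is a
  closed-form difference of regularised incomplete gamma functions
  (evaluated through the upper tail when both endpoints exceed the shape,
  for cancellation-free differences).
* The **mixture** α-integral is evaluated *exactly*: the likelihood is a
  degree-m polynomial in α, built coefficient-by-coefficient in the scaled
  Bernstein basis (all coefficients positive, so the recursion is stable),
  and `∫ α^k (1−α)^{m−k} dα` is a beta function.  A composite-Simpson rule
  on an α grid (201 nodes by default) remains available as a cross-check
  and agrees to ~1e-11.
* The remaining integral over (λ_A, λ_B) uses `n_draws = 4096` draws driven
  by a scrambled 2-D Sobol sequence through a *defensive* importance
  proposal: per dimension, half the quantile mass maps through the
  single-stimulus posterior and half through the AB-updated posterior (the
  posterior refined as if every AB count came from that rate), with
  importance weights bounded by 2 per dimension.  The defensive component
  matters when the AB data conflict with a hypothesis — the integrand then
  lives in the posterior's far tail and plain posterior sampling
  underestimates the marginal by >1e-2 log units.  All draws are
  deterministic given the seed, and the three draw-based marginals share
  one draw set.  Against a brute-force dense-grid reference
  (`spikemux.reference`, Simpson tensor grids over every latent variable)
  the worst error over 80 marginals on small instances is ~6e-5 log units
  at 65,536 draws and ~1e-3 at the default 4096.
* A delta-method Monte-Carlo standard error accompanies every draw-based
  marginal and is propagated to the winning probability.

Exact ties between rate draws (possible only for identical posteriors) are
redrawn.  A/B relabelling is a floating-point-exact symmetry: all
draw-based quantities are computed in a canonical (larger-mean,
smaller-mean) posterior order and mapped back, so swapping the stimulus
labels permutes the single sub-marginals, leaves every category unchanged,
and maps assignment scores s → 1−s and α → 1−α bit-for-bit.

One identity deserves a caveat: with identical rate posteriors the mixture
marginal equals the single marginal only when the two mixture rates are
perfectly correlated; under the independent-draw construction used here the
identity is exact for a single AB count (and in the tight-posterior limit),
and it is tested in that regime.

### Mixing weight and assignment scores

Under the mixture hypothesis the posterior of α (uniform prior) is
accumulated on the Simpson α grid jointly with the rate draws; the package
reports its mean and equal-tail 95% credible interval.  The per-presentation
**assignment score** is the posterior probability that presentation j's
count arose from the A component,
`s_j = E[ α·Poi(y_j|λ_A) / (α·Poi(y_j|λ_A) + (1−α)·Poi(y_j|λ_B)) ]`,
averaged over the same (α, λ_A, λ_B) posterior.  A plug-in variant
(posterior-mean α̂, λ̂_A, λ̂_B) is selectable; the two agree to within ~0.1
on well-separated triplets.  Whether the original colour score of the
trial-matrix figures is this component posterior or a normalised firing
rate is not documented; the component posterior is the default and a
clipped normalised-rate score `(y − λ̂_B)/(λ̂_A − λ̂_B)` is provided as the
alternative.

### Performance of the classifier

On synthetic triplets with λ_A = 20, λ_B = 5 and 20 trials per condition
(500 triplets per regime, screened first), the winning hypothesis matches
the generating regime for 91% (single), 97% (outside), 100% (intermediate)
and 100% (mixture) of triplets.  Mixture recovery as a function of AB trial
count, evaluated on nested samples (common random numbers), rises from
~89% at 5 trials to ~99.7% at 10 and ~100% at 20 — saturating by about 10
dual-stimulus trials, comfortably below the per-triplet trial counts the
generator emulates.  The posterior-mean mixing weight recovers the
generating α with a median absolute error of ~0.07 at 20 AB trials
(uniform α in [0.1, 0.9], rates log-uniform with ratio ≥ 3).

## Pairwise correlation analyses

Spike-count correlations are Pearson correlations of two units' counts over
presentations of one condition, excluding presentations on which either
unit's count lies more than 3 SD from its own condition mean (mean and SD
computed once on all presentations, including the candidate; on outlier-free
data the exclusion is a no-op).  Pairs are labelled *congruent* when both
units' mean counts prefer the same single stimulus, *incongruent* otherwise
(exact ties are excluded).  Every unit pair contributes one record per
qualifying stimulus condition — records are never averaged across
conditions.  Single-stimulus baselines are computed with the same outlier
rule separately on A-alone and B-alone presentations and then pooled, with
an optional split by whether the presented stimulus was the preferred
("driven") one.

Assignment-score correlations are Pearson correlations of two
mixture-classified units' per-presentation scores.  Because the score
orients every unit to the same A-vs-B axis, a pair that genuinely switches
together shows a *positive* score correlation regardless of preference:
congruent pairs replicate the sign of their spike-count correlation and
incongruent pairs invert it — the package's test suite verifies exactly
this sign relation.

Group medians are compared by shuffling the preference labels and
recomputing the median difference 10,000 times; the p-value uses the
add-one rule and the two-sided absolute difference (the sidedness is a
convention choice; the reported p's of the original analysis do not state
it).  Under an exchangeable null the test's type-I error at 0.05 is 0.048
over 1000 replicates.  Per-pair significance, where requested, uses the
t approximation to the null distribution of r, with a permutation option.

## Population trial-score views

For mixture-classified units (winning probability > 0.5) sharing a
condition, the units × trials matrix of assignment scores shows which
stimulus each unit encoded on each trial.  Two comparators frame it:

* **attention-locked** — each row's score multiset is preserved, rows are
  sorted and columns jointly permuted, yielding the maximal across-unit
  coordination the marginals allow (the pattern expected if fluctuations
  were population-wide attention shifts).  Note that even this ceiling is
  below 1 when units' score distributions differ (sorted bimodal rows with
  different A-fractions cannot correlate perfectly); on the default 10-unit,
  18-trial population it is ~0.9.
* **averaging** — every cell drawn iid from `Normal(0.34, 0.10)` clipped to
  [0, 1] (the pattern expected from stable normalisation with no
  fluctuation).  Its pairwise correlations are centred on zero with the
  usual sampling spread `SD(r) ≈ 1/√(n_trials − 1)`; at 50 trials that is
  ≈ 0.14, so individual pair correlations of ±0.2 arise by chance and only
  about half the pairs fall within ±0.1 — a sampling-theory floor, not a
  coordination signal.

Histograms over 10 uniform score bins summarise, per trial, how many units
responded A-like (score ≥ 2/3), B-like (≤ 1/3) or in between, and per unit
how many trials it spent at each level.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, not
the biophysics.  Defaults are the study conditions throughout the tests:
21 A-alone, 21 B-alone and 18 AB presentations per triplet (the recorded
V1 adjacent-stimulus session averages), rates log-uniform over 2–40 counts
per window with preferred/non-preferred ratio ≥ 3, equal regime
proportions, and half the units preferring each stimulus.

Coordination is induced by a single latent per-AB-trial population state
`S_t ~ Bernoulli(β)` (β = 0.5 by default): each mixture unit encodes the
state's stimulus with fidelity φ (default 0.95) and the opposite stimulus
otherwise, then emits Poisson counts at the encoded stimulus's rate.  This
is the simplest mechanism that produces positive spike-count correlations
among congruent-preference pairs and negative among incongruent pairs
while keeping the per-unit mixing weight analytically known,
`α = βφ + (1−β)(1−φ)`.  With φ = 0.95 and ~500 mixture–mixture pairs the
median spike-count correlation is ≈ +0.66 for congruent and ≈ −0.63 for
incongruent pairs (shuffle p < 1e-4); at φ = 0.5 (independent units) both
medians sit within ±0.05 of zero.  These synthetic correlation magnitudes
are larger than typically recorded in cortex because every mixture unit
follows one global state at high fidelity; the *sign pattern*, not the
magnitude, is the validated claim.

Non-mixture regimes emit Poisson counts at λ_A or λ_B (single; target
recorded), at the midpoint (intermediate), or at 1.5×max or 0.5×min
(outside; factor recorded).  Negative-binomial overdispersion with variance
`mean·(1+d)` can replace any Poisson draw to exercise the goodness-of-fit
screen.  Eye traces combine an initial fixation offset (SD 0.06°), slow
AR(1) drift velocity (stationary SD 1 deg/s), and optional injected 0.3°
steps over 6 samples directed toward the fixation centre.

What the generator does **not** emulate — and what passing tests therefore
do not certify on real data: within-presentation temporal dynamics, slow
nonstationarities (adaptation, excitability drift), clustered or multi-state
coordination beyond the single global state, non-Poisson single-stimulus
variability (except as an injected violation), recording artefacts, and any
dependence of rates on eye position.

## Problem sizes and runtime conventions

Full-scale validation (the acceptance harness and `tests/test_acceptance.py`)
uses 20 oracle instances at 65,536 draws, 500 triplets per regime for
recovery, 1000 replicates for the goodness-of-fit and shuffle calibrations
(500 shuffles per replicate in the latter; the add-one threshold at 0.05 is
essentially exact there), 33-unit populations (~500 pairs) for the
correlation structure, and 200 presentations for the detector study.  Large
simulation sweeps use the lighter `FAST_QUAD` quadrature (2048 draws, 101
α nodes), whose per-triplet log-marginal accuracy (~5e-3) is far below any
decision threshold involved.  The numbered drivers under `analysis/` run
reduced sizes of the same studies as a narrative walkthrough.

## Known limitations

* The intrinsic-Bayes-factor construction (training-sample scheme,
  outside-region treatment) follows one concrete operationalisation; other
  published constructions could rank borderline triplets differently.
  Internal consistency is certified against the numerical reference, not
  equivalence with any specific prior implementation.
* The outside hypothesis depends (weakly) on the normalisation cap; the
  sensitivity diagnostic should be consulted for triplets whose winner is
  'outside' with marginal confidence.
* The assignment-score definition for the trial-matrix view is a
  documented choice between two plausible scores (component posterior vs
  normalised rate).
* Synthetic correlation magnitudes are an upper bound on realism (single
  global state, high fidelity); use φ and β to span gentler regimes.
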