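# spikemux

Bayesian detection of neural **multiplexing** — trial-to-trial switching
between stimulus-specific response distributions — in dual-stimulus spike
counts, with population-level correlation analyses of how the switching is
coordinated.  Written for systems neuroscientists analysing trial-aligned
spike counts from visual cortex (or any area) recorded under A-alone,
B-alone and combined-AB stimulus presentations.

## The model

For each *triplet* — one unit's spike counts under stimulus A alone, B
alone, and both together — the single-stimulus responses are modelled as
Poisson with rates λ<sup>A</sup>, λ<sup>B</sup> (units failing a Monte-Carlo
chi-square goodness-of-fit screen at p ≤ 0.10, or whose rates are not
separated by an intrinsic Bayes factor > 3, are excluded).  Four hypotheses
then compete for the combined-stimulus counts y₁…y_m:

| hypothesis | AB distribution |
|---|---|
| single | Poi(λ<sup>AB</sup>), λ<sup>AB</sup> = λ<sup>A</sup> or λ<sup>B</sup> exactly |
| outside | Poi(λ<sup>AB</sup>), λ<sup>AB</sup> outside (min, max) of the two rates |
| intermediate | Poi(λ<sup>AB</sup>), λ<sup>AB</sup> inside the interval |
| mixture | α·Poi(λ<sup>A</sup>) + (1−α)·Poi(λ<sup>B</sup>), α ~ Uniform[0,1] |

Posterior probabilities use equal ¼ priors, Jeffreys' prior λ^(−1/2) on all
rates (conditioned on the single-stimulus data, truncated and renormalised
on each hypothesis region), and are reported with a winning probability
(confidence flags at 0.67 and 0.5).  For mixture units the per-presentation
**assignment score** in [0, 1] — the posterior probability that the count
arose from the A component — localises which stimulus the unit encoded on
each trial.  Pairs of units are then labelled congruent/incongruent by
stimulus preference, and their spike-count and assignment-score
correlations are compared across groups with a 10,000-fold shuffle test of
median differences.

A population that genuinely multiplexes shows the signature: positive
median spike-count correlations for congruent-preference mixture pairs,
negative for incongruent pairs, near-zero single-stimulus baselines, and
assignment-score correlations whose sign matches (congruent) or inverts
(incongruent) the spike-count correlation.

## Worked example

```python
import numpy as np
from spikemux import Triplet, classify_triplet, screen_triplet

rng = np.random.default_rng(3)
t = Triplet("u1", "gratings-1",
            counts_A=rng.poisson(20, 20),                  # A alone
            counts_B=rng.poisson(5, 20),                   # B alone
            counts_AB=np.concatenate([rng.poisson(20, 10), # both: the unit
                                      rng.poisson(5, 10)]))#  switches

screen = screen_triplet(t)
an = classify_triplet(t, screen=screen)
print(an.posterior.winner, round(an.posterior.win_prob, 3))
print("alpha:", round(an.mixture.alpha_mean, 2),
      "scores:", np.round(an.scores[:6], 3))
```

prints

```
mixture 1.0
alpha: 0.51 scores: [1.    0.999 0.999 1.    1.    0.992]
```

The unit's AB counts are best explained by switching between its A-like
(rate 20) and B-like (rate 5) responses with mixing weight ≈ 0.5, and the
first six presentations were all A-like (scores near 1 — they happen to be
high-count trials).

The numbered scripts under `analysis/` run the same machinery end to end on
a coordinated synthetic population (generate → screen → classify →
correlate → population views); `analysis/03_classify_triplets.py` prints a
winner-vs-truth confusion table (91% agreement on the default 30-unit
population) and `analysis/04_pairwise_correlations.py` prints the medians
grid, e.g. mixture–mixture pairs at +0.48 (congruent) vs −0.56
(incongruent), shuffle p = 0.003.  An equivalent single-command pipeline is
available as `spikemux run --config <yaml>`.

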