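"""Triplet assembly and the two pre-analysis exclusion criteria.

A *triplet* is one unit's spike-count samples from the A-alone, B-alone and
combined-AB presentations of a given stimulus pairing.  Before any
dual-stimulus modelling, each triplet must satisfy:

1. both single-stimulus count distributions are consistent with Poisson
   (Monte-Carlo chi-square goodness of fit, retained when p > 0.10), and
2. the two single-stimulus rates are substantially separated (intrinsic
   Bayes factor of ``lambda_A != lambda_B`` over ``lambda_A == lambda_B``
   greater than 3).

Both rules use Jeffreys' improper prior lambda^(-1/2) for Poisson rates; the
intrinsic Bayes factor makes the improper-prior model comparison well defined
by averaging a correction over minimal training samples (one observation per
condition).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

GOF_P_THRESHOLD = 0.10
SEPARATION_BF_THRESHOLD = 3.0
MIN_TRIALS_PER_CONDITION = 5


@dataclass(frozen=True)
class Triplet:
    """One unit x stimulus-pairing analysis unit."""

    unit_id: str
    condition_key: str
    counts_A: np.ndarray
    counts_B: np.ndarray
    counts_AB: np.ndarray

    def __post_init__(self):
        for name in ("counts_A", "counts_B", "counts_AB"):
            arr = np.asarray(getattr(self, name), dtype=int)
            if (arr < 0).any():
                raise ValueError(f"{name} contains negative counts")
            object.__setattr__(self, name, arr)

    def swapped(self) -> "Triplet":
        """The same triplet with the A and B stimulus labels exchanged."""
        return Triplet(self.unit_id, self.condition_key,
                       self.counts_B, self.counts_A, self.counts_AB)


@dataclass(frozen=True)
class ScreenResult:
    gof_p_A: float
    gof_p_B: float
    separation_bf: float
    passed: bool
    fail_reasons: tuple = field(default=())


def assemble_triplets(counts: pd.DataFrame, meta: pd.DataFrame,
                      kept_presentations=None, min_trials: int = MIN_TRIALS_PER_CONDITION,
                      ) -> list[Triplet]:
    """Join a counts table with presentation metadata into triplets.

    Presentations are grouped by ``condition_key`` (the A/B stimulus
    pairing); a triplet is emitted per unit per pairing when every condition
    has at least ``min_trials`` presentations.  Counts are ordered by
    presentation id within a condition so that all units of a pairing share
    the same trial order (required downstream for pairwise correlations).
    """
    meta = meta.copy()
    if "condition_key" not in meta.columns:
        meta["condition_key"] = "all"
    if kept_presentations is not None:
        meta = meta[meta["presentation_id"].isin(set(kept_presentations))]
    merged = counts.merge(meta[["presentation_id", "condition_key", "condition"]],
                          on="presentation_id", how="inner")
    merged = merged.sort_values(["unit_id", "condition", "presentation_id"])
    out = []
    for (unit, key), g in merged.groupby(["unit_id", "condition_key"], sort=True):
        by_cond = {c: sub["count"].to_numpy(int)
                   for c, sub in g.groupby("condition", sort=True)}
        if any(len(by_cond.get(c, ())) < min_trials for c in ("A", "B", "AB")):
            continue
        out.append(Triplet(str(unit), str(key), by_cond["A"], by_cond["B"], by_cond["AB"]))
    return out


# ---------------------------------------------------------------------------
# Monte-Carlo chi-square goodness of fit for the Poisson hypothesis
# ---------------------------------------------------------------------------

def _poisson_chi2_stats(samples: np.ndarray, rates: np.ndarray) -> np.ndarray:
    """Chi-square GOF statistics, one per row of ``samples``.

    Bins are the integers 0, 1, 2, ... with the right tail pooled into a
    single bin so that the pooled tail's expected count is at least 1 under
    Poisson at the row's fitted rate (at minimum two bins are kept).
    """
    samples = np.atleast_2d(samples)
    n_rep, n = samples.shape
    rates = np.atleast_1d(np.asarray(rates, float))
    kmax = int(samples.max(initial=0))
    ks = np.arange(kmax + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        logpmf = ks[None, :] * np.log(rates[:, None]) - rates[:, None] - gammaln(ks + 1)[None, :]
        pmf = np.exp(logpmf)
    pmf[rates == 0] = 0.0
    pmf[rates == 0, 0] = 1.0
    expected = n * pmf
    # tail expected mass at cutoff c: n * P(X >= c)
    tail = n * np.clip(1.0 - np.cumsum(pmf, axis=1), 0.0, None)  # tail[:, c] = n P(X > c)
    tail = np.concatenate([np.full((n_rep, 1), float(n)), tail], axis=1)  # n P(X >= c)
    # largest c in [1, kmax+1] with tail expected >= 1
    ok = tail[:, : kmax + 2] >= 1.0
    cutoff = np.maximum(1, (ok.shape[1] - 1) - np.argmax(ok[:, ::-1], axis=1))
    observed = np.zeros((n_rep, kmax + 2), dtype=float)
    rows = np.repeat(np.arange(n_rep), n)
    np.add.at(observed, (rows, samples.ravel()), 1.0)
    observed = observed[:, : kmax + 1]
    below = ks[None, :] < cutoff[:, None]
    obs_tail = n - np.where(below, observed, 0.0).sum(axis=1)
    exp_tail = np.take_along_axis(tail, cutoff[:, None], axis=1)[:, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = (observed - expected) ** 2 / expected
    terms = np.where(below & (expected > 0), terms, np.where(below & (observed > 0), np.inf, 0.0))
    stat = terms.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tail_term = np.where(exp_tail > 0, (obs_tail - exp_tail) ** 2 / exp_tail,
                             np.where(obs_tail > 0, np.inf, 0.0))
    return stat + tail_term


def poisson_gof_pvalue(counts, n_mc: int = 2000, seed: int = 0) -> float:
    """Monte-Carlo p-value of the chi-square GOF test of the Poisson hypothesis.

    The rate is fit by the sample mean; ``n_mc`` replicate samples of the
    same size are redrawn from the fitted Poisson with the rate refit per
    replicate (parametric bootstrap).  The add-one correction
    ``p = (1 + #{X2_sim >= X2_obs}) / (n_mc + 1)`` keeps p strictly positive.
    """
    counts = np.asarray(counts, dtype=int)
    if counts.ndim != 1 or len(counts) < 3:
        raise ValueError("need at least 3 counts for the goodness-of-fit test")
    if n_mc < 1000:
        raise ValueError("n_mc must be at least 1000")
    lam = counts.mean()
    obs = float(_poisson_chi2_stats(counts[None, :], np.array([lam]))[0])
    rng = np.random.default_rng(seed)
    sims = rng.poisson(lam, size=(n_mc, len(counts)))
    stats = _poisson_chi2_stats(sims, sims.mean(axis=1))
    n_ge = int(np.sum(stats >= obs * (1 - 1e-12) - 1e-12))
    return (1 + n_ge) / (n_mc + 1)


# ---------------------------------------------------------------------------
# Separation Bayes factor (lambda_A != lambda_B vs lambda_A == lambda_B)
# ---------------------------------------------------------------------------

def _jeffreys_log_ml(counts: np.ndarray) -> float:
    """log of the (improper-constant) Jeffreys-prior Poisson marginal likelihood.

    Under prior lambda^(-1/2), integral of the likelihood is
    Gamma(S + 1/2) / n^(S + 1/2) / prod(y_j!).  The arbitrary constant in
    the improper prior cancels in the intrinsic Bayes factor.
    """
    counts = np.asarray(counts, dtype=float)
    s, n = counts.sum(), len(counts)
    return float(gammaln(s + 0.5) - (s + 0.5) * np.log(n) - gammaln(counts + 1).sum())


def separation_bayes_factor(counts_A, counts_B, method: str = "intrinsic",
                            max_training: int = 200, seed: int = 0) -> float:
    """Bayes factor for distinct vs common Poisson rates under Jeffreys priors.

    * ``intrinsic``: arithmetic intrinsic Bayes factor; the raw
      improper-prior Bayes factor is multiplied by the arithmetic mean of its
      inverse over minimal training samples (one observation from each
      condition).  All n_A * n_B training pairs are used when there are at
      most ``max_training``, otherwise ``max_training`` pairs drawn with
      ``seed``.
    * ``fractional``: fractional Bayes factor with training fraction
      b = 2 / (n_A + n_B) (two observations = the minimal training size).
    """
    a = np.asarray(counts_A, dtype=int)
    b = np.asarray(counts_B, dtype=int)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 counts per condition")
    pooled = np.concatenate([a, b])
    log_bf_raw = _jeffreys_log_ml(a) + _jeffreys_log_ml(b) - _jeffreys_log_ml(pooled)
    if method == "intrinsic":
        if len(a) * len(b) <= max_training:
            ai, bj = np.meshgrid(a, b, indexing="ij")
            ai, bj = ai.ravel(), bj.ravel()
        else:
            rng = np.random.default_rng(seed)
            ai = a[rng.integers(0, len(a), max_training)]
            bj = b[rng.integers(0, len(b), max_training)]
        ai = ai.astype(float)
        bj = bj.astype(float)
        # log m0(train) - log m1(train) for each minimal training sample
        lm1 = (gammaln(ai + 0.5) + gammaln(bj + 0.5)
               - gammaln(ai + 1) - gammaln(bj + 1))
        lm0 = (gammaln(ai + bj + 0.5) - (ai + bj + 0.5) * np.log(2.0)
               - gammaln(ai + 1) - gammaln(bj + 1))
        correction = logsumexp(lm0 - lm1) - np.log(len(ai))
        return float(np.exp(log_bf_raw + correction))
    if method == "fractional":
        frac = 2.0 / (len(a) + len(b))
        lt1 = _fractional_log_ml(a, frac) + _fractional_log_ml(b, frac)
        lt0 = _fractional_log_ml(pooled, frac)
        return float(np.exp(log_bf_raw - (lt1 - lt0)))
    raise ValueError(f"unknown method {method!r}")


def _fractional_log_ml(counts: np.ndarray, frac: float) -> float:
    counts = np.asarray(counts, dtype=float)
    s, n = counts.sum(), len(counts)
    return float(gammaln(frac * s + 0.5) - (frac * s + 0.5) * np.log(frac * n)
                 - frac * gammaln(counts + 1).sum())


# ---------------------------------------------------------------------------
# Screening
# ---------------------------------------------------------------------------

def screen_triplet(t: Triplet, gof_threshold: float = GOF_P_THRESHOLD,
                   bf_threshold: float = SEPARATION_BF_THRESHOLD,
                   n_mc: int = 2000, seed: int = 0) -> ScreenResult:
    """Apply both exclusion criteria to one triplet."""
    p_a = poisson_gof_pvalue(t.counts_A, n_mc=n_mc, seed=seed)
    p_b = poisson_gof_pvalue(t.counts_B, n_mc=n_mc, seed=seed + 1)
    bf = separation_bayes_factor(t.counts_A, t.counts_B, seed=seed + 2)
    reasons = []
    if not p_a > gof_threshold:
        reasons.append("A not Poisson")
    if not p_b > gof_threshold:
        reasons.append("B not Poisson")
    if not bf > bf_threshold:
        reasons.append("rates not separated")
    return ScreenResult(p_a, p_b, bf, passed=not reasons, fail_reasons=tuple(reasons))


def screen_dataset(triplets: list[Triplet], n_mc: int = 2000, seed: int = 0,
                   **thresholds) -> pd.DataFrame:
    """Screen every triplet; one row per triplet, seeded deterministically."""
    rows = []
    for i, t in enumerate(triplets):
        res = screen_triplet(t, n_mc=n_mc, seed=seed + 7919 * i, **thresholds)
        rows.append({"unit_id": t.unit_id, "condition_key": t.condition_key,
                     "gof_p_A": res.gof_p_A, "gof_p_B": res.gof_p_B,
                     "separation_bf": res.separation_bf, "passed": res.passed,
                     "fail_reasons": ";".join(res.fail_reasons)})
    return pd.DataFrame(rows)
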