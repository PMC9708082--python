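"""Trial-wise population views of multiplexed responses.

For a set of simultaneously recorded mixture-classified units sharing a
dual-stimulus condition, the trial score matrix colours each (unit, trial)
cell by how A-like the response was (assignment score in [0, 1]).  Two
comparator simulations frame the observed pattern:

* *attention-locked*: every unit keeps its own multiset of scores, but units
  are forced to fluctuate in lockstep (each row sorted, columns jointly
  permuted) — the pattern expected if trial-to-trial fluctuations were
  driven by covert attention shifts shared across the population;
* *averaging*: every cell is an independent draw from a normal distribution
  (defaults: mean 0.34, SD 0.10, clipped to [0, 1]) — the pattern expected
  if units produced a stable normalised average of the two stimuli rather
  than fluctuating.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SELECTION_THRESHOLD = 0.5  # mixture winning probability required for inclusion
AVERAGING_MEAN = 0.34
AVERAGING_SD = 0.10
DEFAULT_BINS = 10


@dataclass(frozen=True)
class TrialScoreMatrix:
    unit_ids: tuple
    trial_ids: tuple
    scores: np.ndarray  # (units, trials) in [0, 1]

    def __post_init__(self):
        s = np.asarray(self.scores, dtype=float)
        if s.shape != (len(self.unit_ids), len(self.trial_ids)):
            raise ValueError("score matrix shape does not match ids")
        if s.size and (s.min() < 0 or s.max() > 1):
            raise ValueError("scores must lie in [0, 1]")
        object.__setattr__(self, "scores", s)

    @property
    def empty(self) -> bool:
        return self.scores.size == 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=list(self.unit_ids),
                            columns=list(self.trial_ids))


def build_trial_matrix(unit_scores: dict, win_probs: dict,
                       selection_threshold: float = SELECTION_THRESHOLD,
                       trial_ids=None) -> TrialScoreMatrix:
    """Assemble scores of units whose mixture winning probability passes selection.

    ``unit_scores`` maps unit_id -> per-trial assignment scores (all units
    share the condition's trial set, identically ordered); ``win_probs``
    maps unit_id -> the winning probability of the mixture model for that
    unit.  Units at or below ``selection_threshold`` are dropped; an empty
    result is returned (flagged via ``.empty``) when none pass.
    """
    selected = [u for u in unit_scores if win_probs.get(u, 0.0) > selection_threshold]
    selected.sort()
    if not selected:
        return TrialScoreMatrix((), (), np.zeros((0, 0)))
    lengths = {len(unit_scores[u]) for u in selected}
    if len(lengths) != 1:
        raise ValueError("units do not share a common trial set")
    n_trials = lengths.pop()
    trial_ids = tuple(trial_ids) if trial_ids is not None else tuple(range(n_trials))
    mat = np.vstack([np.asarray(unit_scores[u], dtype=float) for u in selected])
    return TrialScoreMatrix(tuple(selected), trial_ids, mat)


def score_histograms(m: TrialScoreMatrix, n_bins: int = DEFAULT_BINS,
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-trial and per-unit histograms of scores over uniform [0, 1] bins.

    Rows of the first frame are trials (how many units responded A-like,
    B-like or in between on that trial); rows of the second are units (how
    many trials each unit spent at each response level).
    """
    if m.empty:
        raise ValueError("empty score matrix")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    labels = [f"[{edges[i]:.2f},{edges[i + 1]:.2f})" for i in range(n_bins)]
    idx = np.clip(np.digitize(m.scores, edges[1:-1], right=False), 0, n_bins - 1)
    per_trial = np.zeros((len(m.trial_ids), n_bins), dtype=int)
    per_unit = np.zeros((len(m.unit_ids), n_bins), dtype=int)
    for u in range(idx.shape[0]):
        for t in range(idx.shape[1]):
            per_trial[t, idx[u, t]] += 1
            per_unit[u, idx[u, t]] += 1
    return (pd.DataFrame(per_trial, index=list(m.trial_ids), columns=labels),
            pd.DataFrame(per_unit, index=list(m.unit_ids), columns=labels))


def simulate_attention_locked(m: TrialScoreMatrix, seed: int = 0) -> TrialScoreMatrix:
    """Comparator with maximal across-unit coordination given the row marginals.

    Each unit's multiset of scores is preserved exactly; rows are sorted and
    the columns given one shared random permutation, so every unit is at the
    same quantile of its own score distribution on any given trial.
    """
    if m.empty:
        raise ValueError("empty score matrix")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(m.trial_ids))
    locked = np.sort(m.scores, axis=1)[:, order]
    return TrialScoreMatrix(m.unit_ids, m.trial_ids, locked)


def simulate_averaging(n_units: int, n_trials: int, mean: float = AVERAGING_MEAN,
                       sd: float = AVERAGING_SD, seed: int = 0) -> TrialScoreMatrix:
    """Comparator with no fluctuation structure: iid normal scores, clipped."""
    if n_units < 1 or n_trials < 1:
        raise ValueError("n_units and n_trials must be at least 1")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    rng = np.random.default_rng(seed)
    draws = np.clip(rng.normal(mean, sd, size=(n_units, n_trials)), 0.0, 1.0)
    units = tuple(f"sim{i:03d}" for i in range(n_units))
    return TrialScoreMatrix(units, tuple(range(n_trials)), draws)


def mean_pairwise_correlation(m: TrialScoreMatrix) -> float:
    """Mean Pearson correlation over all unit pairs (NaN-free rows assumed)."""
    if len(m.unit_ids) < 2:
        raise ValueError("need at least two units")
    keep = m.scores.std(axis=1) > 0
    c = np.corrcoef(m.scores[keep])
    iu = np.triu_indices_from(c, k=1)
    return float(c[iu].mean())


def pairwise_correlations(m: TrialScoreMatrix) -> np.ndarray:
    """All pairwise Pearson correlations between unit rows."""
    c = np.corrcoef(m.scores)
    iu = np.triu_indices_from(c, k=1)
    return c[iu]


def rate_based_scores(counts_AB, lam_a: float, lam_b: float) -> np.ndarray:
    """Normalised-rate alternative colour score: (y - lam_B)/(lam_A - lam_B), clipped."""
    y = np.asarray(counts_AB, dtype=float)
    if lam_a == lam_b:
        raise ValueError("rates must differ")
    return np.clip((y - lam_b) / (lam_a - lam_b), 0.0, 1.0)
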