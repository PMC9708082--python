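"""Pairwise spike-count and assignment-score correlation analyses.

Spike-count ("noise") correlations are Pearson correlations of two
simultaneously recorded units' counts across repeated presentations of one
stimulus condition, computed after excluding presentations on which either
unit's count is an outlier (more than 3 SD from its own condition mean).
Pairs are labelled *congruent* when both units respond more strongly to the
same single stimulus and *incongruent* otherwise, and grouped by the
dual-stimulus model category of each unit.  Group medians are compared with
a Monte-Carlo shuffle test that permutes the preference labels.

Assignment-score correlations play the same role on the per-presentation
A-vs-B assignment scores of mixture-classified units: for congruent pairs
they share the sign of the spike-count correlation, for incongruent pairs
the sign flips, which separates shared stimulus selection from generic
firing-rate covariation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

OUTLIER_SD = 3.0
N_SHUFFLES = 10_000
STIMULUS_SETS = ("AB", "A_alone", "B_alone")
MODEL_CLASSES = ("mixture", "intermediate", "single")


@dataclass(frozen=True)
class PreferenceLabel:
    unit_id: str
    condition_key: str
    preferred: str | None  # 'A', 'B', or None on an exact tie (excluded)


def preference(counts_A, counts_B, unit_id: str = "", condition_key: str = "",
               ) -> PreferenceLabel:
    """Stimulus preference by higher mean spike count; exact ties flagged."""
    mean_a = float(np.mean(counts_A))
    mean_b = float(np.mean(counts_B))
    if mean_a > mean_b:
        pref = "A"
    elif mean_b > mean_a:
        pref = "B"
    else:
        pref = None
    return PreferenceLabel(unit_id, condition_key, pref)


def spike_count_correlation(x, y, outlier_sd: float = OUTLIER_SD,
                            ) -> tuple[float, int]:
    """Pearson r of paired counts after the 3-SD outlier exclusion.

    A presentation is dropped when either unit's count deviates more than
    ``outlier_sd`` standard deviations from that unit's mean over all
    presentations of the condition (mean and SD computed once, including
    the candidate).  Returns ``(nan, n)`` when fewer than 3 presentations
    survive or a variance is zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("count vectors must be paired (equal length)")
    keep = _inlier_mask(x, outlier_sd) & _inlier_mask(y, outlier_sd)
    xk, yk = x[keep], y[keep]
    n = int(keep.sum())
    if n < 3 or xk.std() == 0 or yk.std() == 0:
        return float("nan"), n
    r = np.corrcoef(xk, yk)[0, 1]
    return float(r), n


def _inlier_mask(v: np.ndarray, outlier_sd: float) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        return np.ones_like(v, dtype=bool)
    return np.abs(v - v.mean()) <= outlier_sd * sd


def assignment_correlation(s_i, s_j) -> tuple[float, int]:
    """Pearson r of two units' assignment scores over shared AB presentations."""
    s_i = np.asarray(s_i, dtype=float)
    s_j = np.asarray(s_j, dtype=float)
    if s_i.shape != s_j.shape:
        raise ValueError("score vectors must be paired (equal length)")
    if len(s_i) < 3 or s_i.std() == 0 or s_j.std() == 0:
        return float("nan"), len(s_i)
    return float(np.corrcoef(s_i, s_j)[0, 1]), len(s_i)


def label_pair(pref_i: PreferenceLabel, pref_j: PreferenceLabel,
               class_i: str, class_j: str) -> tuple[str, tuple[str, str]]:
    """Congruence of a unit pair plus its unordered model-class combination."""
    if pref_i.condition_key != pref_j.condition_key:
        raise ValueError("preference labels come from different conditions")
    if pref_i.preferred is None or pref_j.preferred is None:
        raise ValueError("tied preference; pair excluded upstream")
    congruence = "congruent" if pref_i.preferred == pref_j.preferred else "incongruent"
    return congruence, tuple(sorted((class_i, class_j)))


# ---------------------------------------------------------------------------
# Shuffle test on group medians
# ---------------------------------------------------------------------------

def median_shuffle_test(group1, group2, n_shuffles: int = N_SHUFFLES,
                        seed: int = 0) -> tuple[float, float]:
    """Two-sided Monte-Carlo test of a difference in group medians.

    The group labels are reshuffled ``n_shuffles`` times and the absolute
    median difference recomputed; ``p = (1 + #{|d_shuf| >= |d_obs|}) /
    (n_shuffles + 1)``.  An observed difference exceeding every shuffle is
    reported as ``p < 1 / n_shuffles`` by this add-one convention.
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    g1 = g1[np.isfinite(g1)]
    g2 = g2[np.isfinite(g2)]
    if g1.size == 0 or g2.size == 0:
        raise ValueError("both groups must be non-empty")
    observed = float(np.median(g1) - np.median(g2))
    pooled = np.concatenate([g1, g2])
    n1, n = g1.size, pooled.size
    rng = np.random.default_rng(seed)
    # vectorised label shuffles in manageable blocks
    count = 0
    block = max(1, min(n_shuffles, int(2e7) // max(n, 1)))
    done = 0
    while done < n_shuffles:
        b = min(block, n_shuffles - done)
        keys = rng.random((b, n))
        order = np.argsort(keys, axis=1)
        perm = pooled[order]
        d = np.median(perm[:, :n1], axis=1) - np.median(perm[:, n1:], axis=1)
        count += int(np.sum(np.abs(d) >= abs(observed) - 1e-12))
        done += b
    p = (1 + count) / (n_shuffles + 1)
    return p, observed


# ---------------------------------------------------------------------------
# Population assembly and summaries
# ---------------------------------------------------------------------------

def build_pair_records(triplets, classifications: dict, scores: dict | None = None,
                       outlier_sd: float = OUTLIER_SD) -> pd.DataFrame:
    """One record per unit pair x condition x stimulus set.

    ``triplets`` is the screened collection (same condition_key implies a
    shared, identically ordered trial set per condition).  ``classifications``
    maps ``(unit_id, condition_key) -> model category`` and ``scores``
    optionally maps the same key to per-AB-presentation assignment scores.
    Pairs with a tied preference are skipped; r values are recorded per
    stimulus set (AB, plus the two single-stimulus baselines).
    """
    scores = scores or {}
    by_key: dict[str, list] = {}
    for t in triplets:
        by_key.setdefault(t.condition_key, []).append(t)
    rows = []
    for key, group in by_key.items():
        prefs = {t.unit_id: preference(t.counts_A, t.counts_B, t.unit_id, key)
                 for t in group}
        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                ti, tj = group[i], group[j]
                pi, pj = prefs[ti.unit_id], prefs[tj.unit_id]
                if pi.preferred is None or pj.preferred is None:
                    continue
                ci = classifications.get((ti.unit_id, key))
                cj = classifications.get((tj.unit_id, key))
                if ci is None or cj is None:
                    continue
                congruence, combo = label_pair(pi, pj, ci, cj)
                for stim_set, xi, xj in (("AB", ti.counts_AB, tj.counts_AB),
                                         ("A_alone", ti.counts_A, tj.counts_A),
                                         ("B_alone", ti.counts_B, tj.counts_B)):
                    if len(xi) != len(xj):
                        continue
                    r_sc, n_used = spike_count_correlation(xi, xj, outlier_sd)
                    r_as = np.nan
                    if stim_set == "AB" and ci == cj == "mixture":
                        si = scores.get((ti.unit_id, key))
                        sj = scores.get((tj.unit_id, key))
                        if si is not None and sj is not None:
                            r_as, _ = assignment_correlation(si, sj)
                    # "driven": the presented single stimulus is the preferred one
                    driven = None
                    if stim_set != "AB" and congruence == "congruent":
                        driven = (stim_set == "A_alone") == (pi.preferred == "A")
                    rows.append({"unit_i": ti.unit_id, "unit_j": tj.unit_id,
                                 "condition_key": key, "stimulus_set": stim_set,
                                 "r_sc": r_sc, "r_as": r_as, "n_used": n_used,
                                 "congruence": congruence,
                                 "class_combo": "|".join(combo),
                                 "pref_i": pi.preferred, "pref_j": pj.preferred,
                                 "driven": driven})
    cols = ["unit_i", "unit_j", "condition_key", "stimulus_set", "r_sc", "r_as",
            "n_used", "congruence", "class_combo", "pref_i", "pref_j", "driven"]
    return pd.DataFrame(rows, columns=cols)


def summarize_population(records: pd.DataFrame, n_shuffles: int = N_SHUFFLES,
                         seed: int = 0, driven_split: bool = False) -> pd.DataFrame:
    """Median correlations per congruence cell, with shuffle-test contrasts.

    Produces the population grid: dual-stimulus (AB) rows for the pooled
    population and for every unordered model-class combination over
    {mixture, intermediate, single}, plus pooled single-stimulus baseline
    rows; each congruent-vs-incongruent contrast carries a shuffle-test p.
    Empty cells are reported with ``n = 0`` and missing medians.
    """
    if records.empty:
        raise ValueError("no pair records to summarise")
    records = records[np.isfinite(records["r_sc"])]
    rows = []
    ab = records[records["stimulus_set"] == "AB"]
    combos = ["all"] + sorted(
        {"|".join(sorted((a, b))) for a in MODEL_CLASSES for b in MODEL_CLASSES})
    for combo in combos:
        sub = ab if combo == "all" else ab[ab["class_combo"] == combo]
        rows.extend(_contrast_rows("AB", combo, sub, n_shuffles, seed))
    single = records[records["stimulus_set"].isin(["A_alone", "B_alone"])]
    rows.extend(_contrast_rows("single", "all", single, n_shuffles, seed + 1))
    if driven_split:
        cong = single[single["congruence"] == "congruent"]
        for flag, name in ((True, "driven"), (False, "not_driven")):
            sub = cong[cong["driven"] == flag]
            rows.append({"stimulus_set": "single", "class_combo": name,
                         "congruence": "congruent", "n": len(sub),
                         "median_r_sc": _med(sub["r_sc"]), "median_r_as": np.nan,
                         "shuffle_p": np.nan})
    return pd.DataFrame(rows)


def _med(v) -> float:
    v = np.asarray(v, dtype=float)
    v = v[np.isfinite(v)]
    return float(np.median(v)) if v.size else np.nan


def _contrast_rows(stim_set, combo, sub, n_shuffles, seed) -> list[dict]:
    cong = sub[sub["congruence"] == "congruent"]
    incong = sub[sub["congruence"] == "incongruent"]
    p = np.nan
    if len(cong) and len(incong):
        p, _ = median_shuffle_test(cong["r_sc"], incong["r_sc"],
                                   n_shuffles=n_shuffles, seed=seed)
    out = []
    for name, grp in (("congruent", cong), ("incongruent", incong)):
        out.append({"stimulus_set": stim_set, "class_combo": combo,
                    "congruence": name, "n": len(grp),
                    "median_r_sc": _med(grp["r_sc"]),
                    "median_r_as": _med(grp["r_as"]),
                    "shuffle_p": p})
    return out


def pair_significance(r: float, n: int) -> float:
    """Two-sided p-value of a single Pearson r under the t approximation."""
    from scipy import stats
    if not np.isfinite(r) or n < 3:
        return float("nan")
    t = r * np.sqrt((n - 2) / max(1e-12, 1 - r * r))
    return float(2 * stats.t.sf(abs(t), n - 2))
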