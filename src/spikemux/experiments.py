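"""Validation experiments: oracle checks, recovery, and calibration studies.

Each function runs one self-contained study of the pipeline's statistical
machinery on synthetic data with known ground truth and returns plain
dictionaries/NumPy values.  They are shared by the test suite, the
validation analysis scripts and the acceptance harness, and are all
deterministic given their seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from dataclasses import replace

from . import reference as ref
from .correlations import build_pair_records, median_shuffle_test
from .models import (FAST_QUAD, QuadConfig, classify_triplet,
                     log_marglik_intermediate, log_marglik_mixture,
                     log_marglik_outside, log_marglik_single, rate_posterior)
from .popview import (build_trial_matrix, mean_pairwise_correlation,
                      pairwise_correlations, simulate_attention_locked,
                      simulate_averaging)
from .screen import Triplet, poisson_gof_pvalue, screen_triplet
from .synth import (EyeTraceConfig, PopulationConfig, generate_eye_traces,
                    generate_triplets)
from .io import detect_microsaccades

REGIMES = ("single", "outside", "intermediate", "mixture")


# ---------------------------------------------------------------------------
# Oracle equivalence of the marginal likelihoods
# ---------------------------------------------------------------------------

def oracle_comparison(n_instances: int = 20, seed: int = 0,
                      n_draws: int = 65536) -> pd.DataFrame:
    """Compare all four log-marginals against the dense-grid reference.

    Instances are small (10 single-stimulus counts per condition, at most 5
    AB counts, rates at most 30) and cycle through AB data generated from
    each of the four regimes so that both well-fitting and badly-fitting
    hypotheses are exercised.  Returns one row per instance with the four
    absolute errors in log units.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_instances):
        lam_a = rng.uniform(8.0, 20.0)
        lam_b = rng.uniform(2.0, lam_a / 3.0)
        ca = rng.poisson(lam_a, 10)
        cb = rng.poisson(lam_b, 10)
        regime = REGIMES[i % 4]
        m = int(rng.integers(3, 6))
        if regime == "single":
            y = rng.poisson(lam_a, m)
        elif regime == "outside":
            y = rng.poisson(1.5 * lam_a, m)
        elif regime == "intermediate":
            y = rng.poisson(0.5 * (lam_a + lam_b), m)
        else:
            y = np.where(rng.random(m) < 0.5, rng.poisson(lam_a, m),
                         rng.poisson(lam_b, m))
        pa, pb = rate_posterior(ca), rate_posterior(cb)
        quad = QuadConfig(n_draws=n_draws, seed=int(rng.integers(2 ** 31)))
        impl = {
            "single": log_marglik_single(y, pa),
            "outside": log_marglik_outside(y, pa, pb, quad)[0],
            "intermediate": log_marglik_intermediate(y, pa, pb, quad)[0],
            "mixture": log_marglik_mixture(y, pa, pb, quad)[0]}
        oracle = {
            "single": ref.ref_log_marglik_single(y, pa),
            "outside": ref.ref_log_marglik_outside(y, pa, pb, n_rate=161, n_inner=401),
            "intermediate": ref.ref_log_marglik_intermediate(y, pa, pb,
                                                             n_rate=161, n_inner=401),
            "mixture": ref.ref_log_marglik_mixture(y, pa, pb, n_rate=161, n_alpha=401)}
        rows.append({"instance": i, "regime": regime, "m": m,
                     **{f"err_{h}": abs(impl[h] - oracle[h]) for h in impl}})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Classifier recovery
# ---------------------------------------------------------------------------

def _regime_triplet(rng, regime: str, lam_a: float, lam_b: float,
                    n_trials: int, m_ab: int) -> Triplet:
    ca = rng.poisson(lam_a, n_trials)
    cb = rng.poisson(lam_b, n_trials)
    if regime == "single":
        lam = lam_a if rng.random() < 0.5 else lam_b
        y = rng.poisson(lam, m_ab)
    elif regime == "outside":
        lam = 1.5 * max(lam_a, lam_b) if rng.random() < 0.5 else 0.5 * min(lam_a, lam_b)
        y = rng.poisson(lam, m_ab)
    elif regime == "intermediate":
        y = rng.poisson(0.5 * (lam_a + lam_b), m_ab)
    elif regime == "mixture":
        y = np.where(rng.random(m_ab) < 0.5, rng.poisson(lam_a, m_ab),
                     rng.poisson(lam_b, m_ab))
    else:
        raise ValueError(regime)
    return Triplet(f"{regime}", "recovery", ca, cb, y)


def classifier_recovery(n_triplets: int = 500, n_trials: int = 20,
                        lam_a: float = 20.0, lam_b: float = 5.0, seed: int = 0,
                        quad: QuadConfig | None = None, n_mc_gof: int = 1000,
                        ) -> dict:
    """Winner-equals-generating-regime rates on screened synthetic triplets.

    For each regime, ``n_triplets`` triplets are generated at the given
    rates and trial counts, screened with the standard criteria, and
    classified; the recovery rate is the fraction of *screened* triplets
    whose winning hypothesis matches the generating regime.
    """
    quad = quad or FAST_QUAD
    rng = np.random.default_rng(seed)
    out = {}
    for regime in REGIMES:
        correct = screened = 0
        for _ in range(n_triplets):
            t = _regime_triplet(rng, regime, lam_a, lam_b, n_trials, n_trials)
            sc = screen_triplet(t, n_mc=n_mc_gof, seed=int(rng.integers(2 ** 31)))
            if not sc.passed:
                continue
            screened += 1
            q = replace(quad, seed=int(rng.integers(2 ** 31)))
            an = classify_triplet(t, quad=q, require_screened=False, fit_mixture=False)
            correct += an.posterior.winner == regime
        out[regime] = {"recovery": correct / max(screened, 1), "n_screened": screened}
    return out


def mixture_recovery_curve(n_triplets: int = 500, n_trials: int = 20,
                           m_values=(5, 10, 20), lam_a: float = 20.0,
                           lam_b: float = 5.0, seed: int = 0,
                           quad: QuadConfig | None = None,
                           n_mc_gof: int = 1000) -> dict:
    """Mixture recovery as a function of the number of AB trials.

    AB samples are nested (the smaller trial counts reuse the first draws
    of the largest), so the curve is evaluated on common random numbers.
    """
    quad = quad or FAST_QUAD
    rng = np.random.default_rng(seed)
    m_max = max(m_values)
    hits = {m: 0 for m in m_values}
    screened = 0
    for _ in range(n_triplets):
        t = _regime_triplet(rng, "mixture", lam_a, lam_b, n_trials, m_max)
        sc = screen_triplet(t, n_mc=n_mc_gof, seed=int(rng.integers(2 ** 31)))
        qseed = int(rng.integers(2 ** 31))
        if not sc.passed:
            continue
        screened += 1
        for m in m_values:
            sub = Triplet(t.unit_id, t.condition_key, t.counts_A, t.counts_B,
                          t.counts_AB[:m])
            q = replace(quad, seed=qseed)
            an = classify_triplet(sub, quad=q, require_screened=False,
                                  fit_mixture=False)
            hits[m] += an.posterior.winner == "mixture"
    return {"n_screened": screened,
            "recovery": {m: hits[m] / max(screened, 1) for m in m_values}}


def alpha_recovery(n_triplets: int = 150, n_trials: int = 20, m_ab: int = 20,
                   seed: int = 0, quad: QuadConfig | None = None) -> dict:
    """Recovery of the generating mixing weight by the posterior mean."""
    quad = quad or FAST_QUAD
    rng = np.random.default_rng(seed)
    errors = []
    for _ in range(n_triplets):
        lam_a = rng.uniform(12.0, 30.0)
        lam_b = rng.uniform(2.0, lam_a / 3.0)
        alpha = rng.uniform(0.1, 0.9)
        ca = rng.poisson(lam_a, n_trials)
        cb = rng.poisson(lam_b, n_trials)
        y = np.where(rng.random(m_ab) < alpha, rng.poisson(lam_a, m_ab),
                     rng.poisson(lam_b, m_ab))
        t = Triplet("a", "c", ca, cb, y)
        q = replace(quad, seed=int(rng.integers(2 ** 31)))
        an = classify_triplet(t, quad=q, require_screened=False)
        errors.append(abs(an.mixture.alpha_mean - alpha))
    return {"median_abs_error": float(np.median(errors)), "n": len(errors)}


# ---------------------------------------------------------------------------
# Goodness-of-fit calibration
# ---------------------------------------------------------------------------

def gof_calibration(n_rep: int = 1000, n: int = 21, dispersion: float | None = None,
                    rate_range=(2.0, 40.0), n_mc: int = 1000, seed: int = 0) -> dict:
    """Exclusion rate of the Poisson screen (p <= 0.10) on known-truth samples.

    With ``dispersion`` unset the samples are truly Poisson and the
    exclusion rate estimates the test's size at the 0.10 threshold; with a
    negative-binomial dispersion the rate estimates its power against
    overdispersion.  Rates are drawn log-uniform over ``rate_range``.
    """
    rng = np.random.default_rng(seed)
    excluded = 0
    for _ in range(n_rep):
        lam = np.exp(rng.uniform(np.log(rate_range[0]), np.log(rate_range[1])))
        if dispersion is None:
            counts = rng.poisson(lam, n)
        else:
            r = lam / dispersion
            counts = rng.negative_binomial(r, 1.0 / (1.0 + dispersion), n)
        p = poisson_gof_pvalue(counts, n_mc=n_mc, seed=int(rng.integers(2 ** 31)))
        excluded += p <= 0.10
    return {"exclusion_rate": excluded / n_rep, "n_rep": n_rep}


# ---------------------------------------------------------------------------
# Correlation structure of the coordinated population
# ---------------------------------------------------------------------------

def correlation_structure(fidelity_phi: float = 0.95, n_units: int = 33,
                          seed: int = 0, n_shuffles: int = 10_000,
                          quad: QuadConfig | None = None,
                          classify: bool = True) -> dict:
    """Median spike-count correlations of mixture-pair groups on the
    coordinated synthetic population (beta = 0.5), with the shuffle test.

    ``n_units = 33`` yields ~500 unit pairs.  With ``classify`` the pairs
    are restricted to units the model comparison itself labels 'mixture'
    (the analysis path); otherwise ground-truth regimes are used.
    """
    quad = quad or FAST_QUAD
    cfg = PopulationConfig(n_units=n_units, regime_proportions=(0, 0, 0, 1.0),
                           fidelity_phi=fidelity_phi, bias_beta=0.5, seed=seed)
    ds = generate_triplets(cfg)
    trips = ds.triplets()
    classes = {}
    for i, t in enumerate(trips):
        if classify:
            q = replace(quad, seed=seed + 104_729 + i)
            an = classify_triplet(t, quad=q, require_screened=False,
                                  fit_mixture=False)
            classes[(t.unit_id, t.condition_key)] = an.posterior.winner
        else:
            classes[(t.unit_id, t.condition_key)] = "mixture"
    rec = build_pair_records(trips, classes)
    mm = rec[(rec["stimulus_set"] == "AB")
             & (rec["class_combo"] == "mixture|mixture")
             & np.isfinite(rec["r_sc"])]
    cong = mm[mm["congruence"] == "congruent"]["r_sc"].to_numpy()
    incong = mm[mm["congruence"] == "incongruent"]["r_sc"].to_numpy()
    p, diff = median_shuffle_test(cong, incong, n_shuffles=n_shuffles, seed=seed)
    return {"median_congruent": float(np.median(cong)),
            "median_incongruent": float(np.median(incong)),
            "n_pairs": int(len(mm)), "shuffle_p": p, "median_difference": diff}


# ---------------------------------------------------------------------------
# Shuffle-test calibration
# ---------------------------------------------------------------------------

def shuffle_calibration(n_rep: int = 1000, n_per_group: int = 20,
                        n_shuffles: int = 500, alpha: float = 0.05,
                        seed: int = 0) -> dict:
    """Type-I error of the median shuffle test under an exchangeable null."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_rep):
        pooled = rng.normal(0.0, 1.0, 2 * n_per_group)
        p, _ = median_shuffle_test(pooled[:n_per_group], pooled[n_per_group:],
                                   n_shuffles=n_shuffles,
                                   seed=int(rng.integers(2 ** 31)))
        rejections += p <= alpha
    return {"type_i_rate": rejections / n_rep, "n_rep": n_rep}


# ---------------------------------------------------------------------------
# Population-view comparators
# ---------------------------------------------------------------------------

def popview_comparators(seed: int = 0, n_units: int = 10,
                        averaging_units: int = 80, averaging_trials: int = 50,
                        quad: QuadConfig | None = None) -> dict:
    """Attention-locked and averaging comparator statistics.

    The attention-locked comparator is applied to the assignment-score
    matrix of a coordinated mixture population; the averaging comparator is
    evaluated on its own iid normal matrix.
    """
    quad = quad or FAST_QUAD
    cfg = PopulationConfig(n_units=n_units, regime_proportions=(0, 0, 0, 1.0),
                           fidelity_phi=0.95, bias_beta=0.5, seed=seed)
    ds = generate_triplets(cfg)
    scores, win = {}, {}
    for i, t in enumerate(ds.triplets()):
        q = replace(quad, seed=seed + 7 * i)
        an = classify_triplet(t, quad=q, require_screened=False)
        scores[t.unit_id] = an.scores
        win[t.unit_id] = an.posterior.p_mixture
    m = build_trial_matrix(scores, win, 0.5)
    locked = simulate_attention_locked(m, seed=seed)
    multisets_ok = all(
        np.array_equal(np.sort(m.scores[i]), np.sort(locked.scores[i]))
        for i in range(len(m.unit_ids)))
    avg = simulate_averaging(averaging_units, averaging_trials, seed=seed)
    r_avg = pairwise_correlations(avg)
    return {
        "n_selected_units": len(m.unit_ids),
        "observed_mean_pairwise_r": mean_pairwise_correlation(m),
        "locked_mean_pairwise_r": mean_pairwise_correlation(locked),
        "locked_preserves_multisets": bool(multisets_ok),
        "averaging_mean_score": float(avg.scores.mean()),
        "averaging_frac_small_r": float(np.mean(np.abs(r_avg) < 0.1)),
    }


# ---------------------------------------------------------------------------
# Microsaccade detection
# ---------------------------------------------------------------------------

def microsaccade_detection(n_presentations: int = 200, amplitude: float = 0.3,
                           seed: int = 0) -> dict:
    """Recall and false-event rate of the velocity-threshold detector.

    Half the synthetic fixation traces carry one injected step of the given
    amplitude at a known time; recall is the fraction of injected events
    recovered (any detected interval overlapping the injection window,
    padded by 5 samples), and the false-event rate is detections per
    event-free presentation.
    """
    cfg = EyeTraceConfig(n_presentations=n_presentations,
                         saccade_amplitude=amplitude, seed=seed)
    traces, truth = generate_eye_traces(cfg)
    hits = misses = false_events = clean = 0
    for row in truth.itertuples(index=False):
        events = detect_microsaccades(traces[row.presentation_id])
        if row.has_event:
            ok = any(s <= row.end_idx + 5 and e >= row.start_idx - 5
                     for s, e in events)
            hits += ok
            misses += not ok
        else:
            clean += 1
            false_events += len(events)
    n_inj = hits + misses
    return {"recall": hits / max(n_inj, 1),
            "false_event_rate": false_events / max(clean, 1),
            "n_injected": n_inj, "n_clean": clean}
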