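"""Ground-truth-labelled synthetic populations of dual-stimulus responses.

The generator emulates the statistical structure the analysis assumes:
Poisson single-stimulus responses with well-separated rates, the four
dual-stimulus response regimes, and population-level coordination of the
mixture units' trial-to-trial switching.

Coordination is induced by a single latent per-AB-trial population state
(which of the two stimuli the population is biased toward on that trial,
drawn Bernoulli(``bias_beta``) independently across trials).  Each mixture
unit *encodes* the population state with probability ``fidelity_phi`` and
the opposite stimulus otherwise, then emits a Poisson count at the rate of
the encoded stimulus.  This is the simplest mechanism that yields positive
spike-count correlations among congruent-preference pairs and negative
among incongruent-preference pairs while keeping the per-unit mixing weight
analytically known: the probability of encoding stimulus A is
``alpha = beta * phi + (1 - beta) * (1 - phi)`` for every mixture unit.

Trial-count defaults (21 single-stimulus, 18 dual-stimulus presentations
per triplet) follow the recorded V1 adjacent-stimulus sessions the analysis
is modelled on.  Firing rates are log-uniform over ``rate_range`` (counts
per 200 ms window) with the preferred/non-preferred ratio at least
``min_rate_ratio`` so that triplets genuinely satisfy the separation
screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .io import EyeTrace
from .screen import Triplet

REGIMES = ("single", "outside", "intermediate", "mixture")


@dataclass(frozen=True)
class PopulationConfig:
    n_units: int = 30
    trials_A: int = 21
    trials_B: int = 21
    trials_AB: int = 18
    rate_range: tuple = (2.0, 40.0)
    min_rate_ratio: float = 3.0
    regime_proportions: tuple = (0.25, 0.25, 0.25, 0.25)
    pref_A_fraction: float = 0.5
    bias_beta: float = 0.5       # P(population state = A) per AB trial
    fidelity_phi: float = 0.95   # P(a mixture unit encodes the population state)
    overdispersion: float | None = None
    condition_key: str = "cond-01"
    session_id: str = "synthetic"
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.regime_proportions) - 1.0) > 1e-9:
            raise ValueError("regime_proportions must sum to 1")
        if len(self.regime_proportions) != len(REGIMES):
            raise ValueError("regime_proportions must have 4 entries")
        if min(self.trials_A, self.trials_B, self.trials_AB) < 5:
            raise ValueError("need at least 5 trials per condition")
        lo, hi = self.rate_range
        if lo <= 0 or hi <= lo:
            raise ValueError("rate_range must be a positive increasing interval")
        if hi / lo < self.min_rate_ratio:
            raise ValueError("rate_range too narrow for min_rate_ratio")
        if not 0.5 <= self.fidelity_phi <= 1.0:
            raise ValueError("fidelity_phi must lie in [0.5, 1]")
        if not 0.0 <= self.bias_beta <= 1.0:
            raise ValueError("bias_beta must lie in [0, 1]")


@dataclass
class SyntheticDataset:
    config: PopulationConfig
    counts: pd.DataFrame        # unit_id, presentation_id, count
    meta: pd.DataFrame          # presentation metadata (spike_io schema)
    truth: pd.DataFrame         # per-unit ground truth
    latent_states: np.ndarray   # per-AB-trial population state, 1 = A
    presentation_ids: dict = field(default_factory=dict)  # condition -> ids

    def triplets(self) -> list[Triplet]:
        wide = self.counts.pivot(index="unit_id", columns="presentation_id",
                                 values="count")
        out = []
        for unit in self.truth["unit_id"]:
            out.append(Triplet(
                unit, self.config.condition_key,
                wide.loc[unit, self.presentation_ids["A"]].to_numpy(int),
                wide.loc[unit, self.presentation_ids["B"]].to_numpy(int),
                wide.loc[unit, self.presentation_ids["AB"]].to_numpy(int)))
        return out

    def to_csv(self, outdir) -> None:
        """Write the spike_io-schema CSV bundle plus the ground-truth table."""
        from pathlib import Path
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.counts.to_csv(outdir / "counts.csv", index=False)
        self.meta.to_csv(outdir / "metadata.csv", index=False)
        self.truth.to_csv(outdir / "truth.csv", index=False)

    def spike_events(self, window) -> pd.DataFrame:
        """Expand counts into uniform spike times inside the counting window."""
        rng = np.random.default_rng(self.config.seed + 986_527)
        reps = self.counts["count"].to_numpy()
        times = rng.uniform(window.start_ms, window.end_ms, int(reps.sum()))
        return pd.DataFrame({
            "unit_id": np.repeat(self.counts["unit_id"].to_numpy(), reps),
            "presentation_id": np.repeat(self.counts["presentation_id"].to_numpy(), reps),
            "time_ms": times})


# ---------------------------------------------------------------------------
# Component samplers
# ---------------------------------------------------------------------------

def sample_unit_rates(cfg: PopulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Log-uniform rate pairs with preferred/non-preferred ratio >= min_rate_ratio."""
    lo, hi = cfg.rate_range
    lam_hi = np.exp(rng.uniform(np.log(lo * cfg.min_rate_ratio), np.log(hi), cfg.n_units))
    lam_lo = np.exp(rng.uniform(np.log(lo), np.log(lam_hi / cfg.min_rate_ratio)))
    n_pref_a = int(round(cfg.pref_A_fraction * cfg.n_units))
    prefers_a = np.zeros(cfg.n_units, dtype=bool)
    prefers_a[rng.permutation(cfg.n_units)[:n_pref_a]] = True
    lam_a = np.where(prefers_a, lam_hi, lam_lo)
    lam_b = np.where(prefers_a, lam_lo, lam_hi)
    return pd.DataFrame({
        "unit_id": [f"u{i:03d}" for i in range(cfg.n_units)],
        "lam_A": lam_a, "lam_B": lam_b,
        "preference": np.where(prefers_a, "A", "B")})


def sample_latent_states(cfg: PopulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-AB-trial population state: 1 encodes stimulus A, 0 stimulus B."""
    return (rng.random(cfg.trials_AB) < cfg.bias_beta).astype(int)


def _assign_regimes(cfg: PopulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Largest-remainder allocation of units to regimes, then shuffled."""
    target = np.array(cfg.regime_proportions) * cfg.n_units
    counts = np.floor(target).astype(int)
    remainder = cfg.n_units - counts.sum()
    order = np.argsort(-(target - counts))
    counts[order[:remainder]] += 1
    regimes = np.repeat(np.array(REGIMES), counts)
    return rng.permutation(regimes)


def _draw_counts(rng: np.random.Generator, lam, size=None,
                 dispersion: float | None = None) -> np.ndarray:
    """Poisson draws, or negative-binomial with variance mean*(1+dispersion)."""
    lam = np.asarray(lam, dtype=float)
    if dispersion is None or dispersion == 0:
        return rng.poisson(lam, size=size)
    r = lam / dispersion
    p = 1.0 / (1.0 + dispersion)
    return rng.negative_binomial(np.where(r > 0, r, 1e-12), p, size=size)


def inject_overdispersion(counts, dispersion: float, seed: int = 0) -> np.ndarray:
    """Redraw a count sample as negative binomial with the same mean.

    The replacement keeps the sample-mean rate but inflates the variance to
    ``mean * (1 + dispersion)``, violating the Poisson hypothesis that the
    goodness-of-fit screen tests.
    """
    counts = np.asarray(counts, dtype=float)
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    rng = np.random.default_rng(seed)
    lam = counts.mean()
    return _draw_counts(rng, np.full(counts.shape, lam), dispersion=dispersion)


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

def generate_triplets(cfg: PopulationConfig) -> SyntheticDataset:
    """Generate a full population dataset with per-unit ground truth."""
    rng = np.random.default_rng(cfg.seed)
    rates = sample_unit_rates(cfg, rng)
    regimes = _assign_regimes(cfg, rng)
    states = sample_latent_states(cfg, rng)  # shared across the population

    pids = {
        "A": [f"{cfg.condition_key}-A-{i:03d}" for i in range(cfg.trials_A)],
        "B": [f"{cfg.condition_key}-B-{i:03d}" for i in range(cfg.trials_B)],
        "AB": [f"{cfg.condition_key}-AB-{i:03d}" for i in range(cfg.trials_AB)],
    }
    alpha_pop = cfg.bias_beta * cfg.fidelity_phi + (1 - cfg.bias_beta) * (1 - cfg.fidelity_phi)

    count_rows, truth_rows = [], []
    for i, row in enumerate(rates.itertuples(index=False)):
        lam_a, lam_b = row.lam_A, row.lam_B
        regime = regimes[i]
        c_a = _draw_counts(rng, np.full(cfg.trials_A, lam_a), dispersion=cfg.overdispersion)
        c_b = _draw_counts(rng, np.full(cfg.trials_B, lam_b), dispersion=cfg.overdispersion)
        single_target = outside_factor = None
        alpha_true = np.nan
        alpha_emp = np.nan
        if regime == "single":
            single_target = rng.choice(["A", "B"])
            lam_ab = np.full(cfg.trials_AB, lam_a if single_target == "A" else lam_b)
        elif regime == "outside":
            outside_factor = rng.choice([1.5, 0.5])
            lam_ab = np.full(cfg.trials_AB,
                             1.5 * max(lam_a, lam_b) if outside_factor == 1.5
                             else 0.5 * min(lam_a, lam_b))
        elif regime == "intermediate":
            lam_ab = np.full(cfg.trials_AB, 0.5 * (lam_a + lam_b))
        else:  # mixture: encode the population state with fidelity phi
            follows = rng.random(cfg.trials_AB) < cfg.fidelity_phi
            encodes_a = np.where(follows, states, 1 - states).astype(bool)
            lam_ab = np.where(encodes_a, lam_a, lam_b)
            alpha_true = alpha_pop
            alpha_emp = float(encodes_a.mean())
        c_ab = _draw_counts(rng, lam_ab, dispersion=cfg.overdispersion)
        for cond, arr in (("A", c_a), ("B", c_b), ("AB", c_ab)):
            count_rows.extend(zip([row.unit_id] * len(arr), pids[cond], arr.tolist()))
        truth_rows.append({
            "unit_id": row.unit_id, "regime": regime, "lam_A": lam_a, "lam_B": lam_b,
            "preference": row.preference, "alpha_true": alpha_true,
            "alpha_empirical": alpha_emp, "single_target": single_target,
            "outside_factor": outside_factor})

    counts = pd.DataFrame(count_rows, columns=["unit_id", "presentation_id", "count"])
    meta_rows = []
    for cond in ("A", "B", "AB"):
        for pid in pids[cond]:
            meta_rows.append({
                "presentation_id": pid, "session_id": cfg.session_id,
                "condition_key": cfg.condition_key, "condition": cond,
                "stim_a_id": "stimA" if cond in ("A", "AB") else "",
                "stim_b_id": "stimB" if cond in ("B", "AB") else "",
                "correct": True, "attended_in_rf": False})
    return SyntheticDataset(cfg, counts, pd.DataFrame(meta_rows),
                            pd.DataFrame(truth_rows), states, pids)


# ---------------------------------------------------------------------------
# Synthetic eye traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EyeTraceConfig:
    n_presentations: int = 200
    duration_ms: float = 300.0
    sample_rate: float = 500.0
    scatter_sd: float = 0.06        # SD of the initial fixation offset (deg)
    drift_speed_sd: float = 1.0     # stationary SD of drift velocity (deg/s)
    drift_ar: float = 0.9           # AR(1) coefficient of the drift velocity
    saccade_fraction: float = 0.5   # fraction of presentations given one event
    saccade_amplitude: float = 0.3  # deg
    saccade_samples: int = 6        # ramp duration of the injected step
    seed: int = 0


def generate_eye_traces(cfg: EyeTraceConfig) -> tuple[dict, pd.DataFrame]:
    """Fixational drift traces with step-like microsaccades at known times.

    Between events the gaze performs slow ocular drift: the velocity is a
    smooth AR(1) process with stationary SD ``drift_speed_sd`` (about 1
    deg/s, far below the microsaccade detection threshold) and the position
    integrates it from a small random fixation offset.  Injected events are
    position steps of ``saccade_amplitude`` over ``saccade_samples``
    samples, directed toward the fixation centre so traces respect the
    +/-0.5 deg window.  Returns the traces and a truth table of injected
    event sample intervals.
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_ms * cfg.sample_rate / 1000.0))
    sigma_v = cfg.drift_speed_sd * np.sqrt(1 - cfg.drift_ar ** 2)
    traces, rows = {}, []
    for i in range(cfg.n_presentations):
        pid = f"p{i:04d}"
        vel = np.empty((2, n))
        vel[:, 0] = rng.normal(0.0, cfg.drift_speed_sd, 2)
        innov = rng.normal(0.0, sigma_v, (2, n - 1))
        for t in range(1, n):
            vel[:, t] = cfg.drift_ar * vel[:, t - 1] + innov[:, t - 1]
        xy = rng.normal(0.0, cfg.scatter_sd, 2)[:, None] \
            + np.cumsum(vel, axis=1) / cfg.sample_rate
        has_event = rng.random() < cfg.saccade_fraction
        start = end = -1
        if has_event:
            start = int(rng.integers(10, n - cfg.saccade_samples - 10))
            end = start + cfg.saccade_samples
            pos = xy[:, start]
            direction = -pos / max(np.linalg.norm(pos), 1e-6)
            ramp = np.linspace(0.0, cfg.saccade_amplitude, cfg.saccade_samples)
            xy[:, start:end] += direction[:, None] * ramp[None, :]
            xy[:, end:] += direction[:, None] * cfg.saccade_amplitude
        xy = np.clip(xy, -0.49, 0.49)
        traces[pid] = EyeTrace(pid, cfg.sample_rate, xy[0], xy[1])
        rows.append({"presentation_id": pid, "has_event": has_event,
                     "start_idx": start, "end_idx": end})
    return traces, pd.DataFrame(rows)


def config_from_dict(d: dict) -> PopulationConfig:
    known = {f.name for f in PopulationConfig.__dataclass_fields__.values()}
    kwargs = {k: v for k, v in d.items() if k in known}
    for key in ("rate_range", "regime_proportions"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    return PopulationConfig(**kwargs)
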