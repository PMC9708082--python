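"""Trial-aligned spike and eye-trace ingestion.

Spike counts are taken in a fixed 200 ms window offset by the typical visual
response latency of the area under study (30-230 ms after stimulus onset for
V1, 50-250 ms for V4).  Presentations are screened with the experiment's
behavioural rules: only correctly performed trials, with gaze inside a small
fixation window (default +/-0.5 deg) and no microsaccade during the stimulus,
and with attention directed away from the receptive fields, are analysed.

All tabular inputs are plain CSV:

* spikes:   ``unit_id, presentation_id, time_ms`` (one row per spike)
* metadata: ``presentation_id, session_id, condition_key, condition,
  stim_a_id, stim_b_id, correct, attended_in_rf``
* eye:      ``presentation_id, t_ms, x_deg, y_deg``
* counts:   ``unit_id, presentation_id, count`` (pre-counted alternative)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

CONDITIONS = ("A", "B", "AB")

#: (start_ms, end_ms) of the response-latency-corrected counting window.
AREA_WINDOWS = {"V1": (30.0, 230.0), "V4": (50.0, 250.0)}


@dataclass(frozen=True)
class AreaWindow:
    """A 200 ms spike-counting window for one cortical area."""

    area: str
    start_ms: float
    end_ms: float

    def __post_init__(self) -> None:
        if abs((self.end_ms - self.start_ms) - 200.0) > 1e-9:
            raise ValueError("counting window must span exactly 200 ms")

    @classmethod
    def for_area(cls, area: str) -> "AreaWindow":
        try:
            start, end = AREA_WINDOWS[area]
        except KeyError:
            raise ValueError(f"unknown area {area!r}; expected one of {sorted(AREA_WINDOWS)}")
        return cls(area, start, end)


@dataclass(frozen=True)
class EyeTrace:
    """Horizontal/vertical eye position (degrees) for one presentation."""

    presentation_id: str
    sample_rate: float  # Hz
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if len(self.x) != len(self.y):
            raise ValueError("x and y must have equal length")


@dataclass
class ExclusionLog:
    """First failing rule per excluded presentation, plus soft warnings."""

    excluded: dict = field(default_factory=dict)  # presentation_id -> reason
    warnings: dict = field(default_factory=dict)  # presentation_id -> note

    def to_frame(self) -> pd.DataFrame:
        rows = [{"presentation_id": p, "kind": "excluded", "reason": r}
                for p, r in self.excluded.items()]
        rows += [{"presentation_id": p, "kind": "warning", "reason": r}
                 for p, r in self.warnings.items()]
        return pd.DataFrame(rows, columns=["presentation_id", "kind", "reason"])


# ---------------------------------------------------------------------------
# CSV readers
# ---------------------------------------------------------------------------

def read_spikes(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"unit_id": str, "presentation_id": str})
    _require(df, ["unit_id", "presentation_id", "time_ms"], "spikes")
    if not np.isfinite(df["time_ms"]).all():
        raise ValueError("spike times must be finite")
    return df


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"presentation_id": str}, keep_default_na=False)
    _require(df, ["presentation_id", "condition", "correct", "attended_in_rf"], "metadata")
    bad = ~df["condition"].isin(CONDITIONS)
    if bad.any():
        raise ValueError(f"unknown condition labels: {sorted(df.loc[bad, 'condition'].unique())}")
    for col in ("correct", "attended_in_rf"):
        df[col] = df[col].astype(str).str.lower().isin(("true", "1", "1.0", "yes"))
    return df


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"unit_id": str, "presentation_id": str})
    _require(df, ["unit_id", "presentation_id", "count"], "counts")
    if (df["count"] < 0).any():
        raise ValueError("spike counts must be non-negative")
    return df


def read_eye(path) -> dict[str, EyeTrace]:
    df = pd.read_csv(path, dtype={"presentation_id": str})
    _require(df, ["presentation_id", "t_ms", "x_deg", "y_deg"], "eye")
    traces = {}
    for pid, g in df.groupby("presentation_id", sort=True):
        g = g.sort_values("t_ms")
        t = g["t_ms"].to_numpy(float)
        if len(t) < 2:
            raise ValueError(f"eye trace for {pid} has fewer than 2 samples")
        dt = np.median(np.diff(t))
        traces[str(pid)] = EyeTrace(str(pid), 1000.0 / dt,
                                    g["x_deg"].to_numpy(float), g["y_deg"].to_numpy(float))
    return traces


def _require(df: pd.DataFrame, cols, what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what} file is missing columns {missing}")


# ---------------------------------------------------------------------------
# Spike counting
# ---------------------------------------------------------------------------

def count_spikes_in_window(spikes: pd.DataFrame, window: AreaWindow,
                           units=None, presentations=None) -> pd.DataFrame:
    """Count spikes with ``start_ms <= t < end_ms`` per (unit, presentation).

    The window is half-open so that abutting windows never double-count a
    spike.  ``units`` / ``presentations`` widen the output grid so that
    silent unit-presentation combinations appear with count 0.
    """
    units = sorted(set(spikes["unit_id"]) | (set(units) if units is not None else set()))
    presentations = sorted(set(spikes["presentation_id"])
                           | (set(presentations) if presentations is not None else set()))
    inside = spikes[(spikes["time_ms"] >= window.start_ms) & (spikes["time_ms"] < window.end_ms)]
    tally = inside.groupby(["unit_id", "presentation_id"]).size()
    grid = pd.MultiIndex.from_product([units, presentations], names=["unit_id", "presentation_id"])
    out = tally.reindex(grid, fill_value=0).rename("count").reset_index()
    out["count"] = out["count"].astype(int)
    return out


# ---------------------------------------------------------------------------
# Microsaccade detection
# ---------------------------------------------------------------------------

#: Moving-average length (samples) applied to the speed trace before
#: thresholding.  The detection rule itself is speed > mean + 6 SD of the
#: steady-fixation speed.
SPEED_SMOOTH_SAMPLES = 5
VELOCITY_SD_FACTOR = 6.0


def eye_speed(trace: EyeTrace, smooth: int = SPEED_SMOOTH_SAMPLES) -> np.ndarray:
    """Smoothed gaze speed in deg/s (central finite differences)."""
    if trace.sample_rate <= 0:
        raise ValueError("sample_rate must be positive")
    if len(trace.x) < 3:
        raise ValueError("trace must have at least 3 samples")
    vx = np.gradient(trace.x) * trace.sample_rate
    vy = np.gradient(trace.y) * trace.sample_rate
    speed = np.hypot(vx, vy)
    if smooth > 1:
        pad = smooth // 2
        padded = np.pad(speed, pad, mode="edge")
        speed = np.convolve(padded, np.ones(smooth) / smooth, mode="valid")[: len(speed)]
    return speed


def detect_microsaccades(trace: EyeTrace, baseline_stats=None,
                         sd_factor: float = VELOCITY_SD_FACTOR,
                         min_samples: int = 1) -> list[tuple[int, int]]:
    """Return ``[(start_idx, end_idx), ...]`` (half-open) of speed threshold crossings.

    ``baseline_stats`` is an optional ``(mean, sd)`` of steady-fixation speed.
    When absent it is estimated from the trace itself in two passes: a robust
    first pass (median and MAD-based SD, insensitive to the saccades
    themselves) flags candidate event samples, and the baseline mean/SD are
    then computed over the remaining steady-fixation samples.
    """
    speed = eye_speed(trace)
    if baseline_stats is None:
        med = float(np.median(speed))
        robust_sd = 1.4826 * float(np.median(np.abs(speed - med)))
        mask = speed <= med + sd_factor * robust_sd
        if not mask.any():
            mask = np.ones_like(speed, dtype=bool)
        mean, sd = float(speed[mask].mean()), float(speed[mask].std())
    else:
        mean, sd = baseline_stats
        if sd < 0:
            raise ValueError("baseline SD must be non-negative")
    above = speed > mean + sd_factor * sd
    return _runs(above, min_samples)


def _runs(mask: np.ndarray, min_samples: int) -> list[tuple[int, int]]:
    edges = np.flatnonzero(np.diff(np.concatenate(([0], mask.astype(int), [0]))))
    out = []
    for start, end in zip(edges[::2], edges[1::2]):
        if end - start >= min_samples:
            out.append((int(start), int(end)))
    return out


# ---------------------------------------------------------------------------
# Presentation-level exclusion
# ---------------------------------------------------------------------------

FIXATION_HALFWIDTH_DEG = 0.5


def filter_presentations(meta: pd.DataFrame, traces: dict[str, EyeTrace] | None = None,
                         fixation_halfwidth: float = FIXATION_HALFWIDTH_DEG,
                         ) -> tuple[list[str], ExclusionLog]:
    """Apply the behavioural exclusion rules; return kept ids and a log.

    A presentation is kept iff the trial was correct, attention was directed
    away from the recorded receptive fields, gaze stayed within the fixation
    window throughout, and no microsaccade was detected.  The log records the
    first failing rule per excluded presentation; presentations without an
    eye trace are kept with the eye rules skipped and a warning logged.
    """
    traces = traces or {}
    log = ExclusionLog()
    kept: list[str] = []
    for row in meta.itertuples(index=False):
        pid = str(row.presentation_id)
        if not row.correct:
            log.excluded[pid] = "incorrect_trial"
            continue
        if getattr(row, "attended_in_rf", False):
            log.excluded[pid] = "attended_in_rf"
            continue
        trace = traces.get(pid)
        if trace is None:
            if traces:
                log.warnings[pid] = "no_eye_trace; eye rules skipped"
            kept.append(pid)
            continue
        if np.abs(trace.x).max() > fixation_halfwidth or np.abs(trace.y).max() > fixation_halfwidth:
            log.excluded[pid] = "fixation_break"
            continue
        if detect_microsaccades(trace):
            log.excluded[pid] = "microsaccade"
            continue
        kept.append(pid)
    return kept, log


# ---------------------------------------------------------------------------
# Firing-rate vs fixational-scatter control
# ---------------------------------------------------------------------------

def eye_rate_correlation(counts: pd.DataFrame, traces: dict[str, EyeTrace],
                         stimulus_axis=(1.0, 0.0), alpha: float = 0.05) -> pd.DataFrame:
    """Correlate per-presentation counts with eye position along the stimulus axis.

    The eye-position covariate is the presentation-mean gaze position
    projected onto the unit vector connecting the two stimulus locations.
    Returns one row per unit with Pearson r, its p-value, n, and flags.
    Units with zero variance in either variable get ``r = NaN`` and
    ``undefined = True``.
    """
    axis = np.asarray(stimulus_axis, float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("stimulus_axis must be a nonzero vector")
    axis = axis / norm
    proj = {pid: float(np.mean(tr.x) * axis[0] + np.mean(tr.y) * axis[1])
            for pid, tr in traces.items()}
    rows = []
    for unit, g in counts.groupby("unit_id", sort=True):
        g = g[g["presentation_id"].isin(proj)]
        if len(g) < 3:
            rows.append({"unit_id": unit, "r": np.nan, "p": np.nan, "n": len(g),
                         "undefined": True, "significant": False})
            continue
        x = g["count"].to_numpy(float)
        y = np.array([proj[p] for p in g["presentation_id"]])
        if x.std() == 0 or y.std() == 0:
            rows.append({"unit_id": unit, "r": np.nan, "p": np.nan, "n": len(g),
                         "undefined": True, "significant": False})
            continue
        r, p = stats.pearsonr(x, y)
        rows.append({"unit_id": unit, "r": float(r), "p": float(p), "n": len(g),
                     "undefined": False, "significant": bool(p < alpha)})
    return pd.DataFrame(rows)
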