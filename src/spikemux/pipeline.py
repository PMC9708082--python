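"""End-to-end orchestration: ingest -> screen -> classify -> correlate -> summarise.

A run is driven by a single :class:`RunConfig` (loadable from YAML).  Every
stage writes self-describing CSV/JSON outputs stamped with the
configuration hash and seed, and a rerun with the same configuration
produces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import correlations as corr
from . import io as spio
from . import popview
from .models import FAST_QUAD, QuadConfig, classify_triplet
from .screen import Triplet, assemble_triplets, screen_dataset
from .synth import PopulationConfig, SyntheticDataset, config_from_dict, generate_triplets

STAGES = ("simulate", "ingest", "screen", "classify", "correlate", "summarize", "popview")


@dataclass
class RunConfig:
    """Everything needed to reproduce a full pipeline run."""

    outdir: str = "results/run"
    seed: int = 0
    area: str = "V1"
    synthetic: dict | None = None          # PopulationConfig fields, or None
    spikes_csv: str | None = None          # raw-spike input path (with metadata_csv)
    counts_csv: str | None = None          # pre-counted alternative
    metadata_csv: str | None = None
    eye_csv: str | None = None
    gof_p_threshold: float = 0.10
    separation_bf_threshold: float = 3.0
    win_prob_confident: float = 0.67
    win_prob_majority: float = 0.5
    outlier_sd: float = 3.0
    n_shuffles: int = 10_000
    fixation_halfwidth: float = 0.5
    quad: dict = field(default_factory=dict)  # QuadConfig overrides

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in raw.items() if k in known})

    def quad_config(self) -> QuadConfig:
        base = asdict(FAST_QUAD)
        base.update(self.quad)
        base["seed"] = self.seed
        return QuadConfig(**base)

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage; returns the report dictionary (also written to disk)."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report = {"config_hash": cfg.hash(), "seed": cfg.seed, "stages": {}}
    state: dict = {}
    for stage in STAGES:
        if stage == "simulate" and cfg.synthetic is None:
            continue
        if stage == "ingest" and cfg.synthetic is not None:
            continue
        t0 = time.perf_counter()
        STAGE_FUNCS[stage](cfg, state, out, report)
        report["stages"][stage] = {"seconds": round(time.perf_counter() - t0, 3)}
    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2, default=_json_default,
                                      sort_keys=True))
    return report


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: RunConfig, state, out: Path, report) -> None:
    pc = config_from_dict({**(cfg.synthetic or {}), "seed": cfg.seed})
    ds: SyntheticDataset = generate_triplets(pc)
    ds.to_csv(out)
    state["dataset"] = ds
    state["triplets"] = ds.triplets()
    report["synthetic_config"] = asdict(pc)


def stage_ingest(cfg: RunConfig, state, out: Path, report) -> None:
    meta = spio.read_metadata(cfg.metadata_csv)
    traces = spio.read_eye(cfg.eye_csv) if cfg.eye_csv else {}
    kept, log = spio.filter_presentations(meta, traces, cfg.fixation_halfwidth)
    log.to_frame().to_csv(out / "exclusions.csv", index=False)
    if cfg.counts_csv:
        counts = spio.read_counts(cfg.counts_csv)
    elif cfg.spikes_csv:
        window = spio.AreaWindow.for_area(cfg.area)
        spikes = spio.read_spikes(cfg.spikes_csv)
        counts = spio.count_spikes_in_window(
            spikes, window, presentations=meta["presentation_id"])
    else:
        raise ValueError("need counts_csv or spikes_csv when not synthetic")
    counts = counts[counts["presentation_id"].isin(set(kept))]
    counts.to_csv(out / "counts.csv", index=False)
    state["triplets"] = assemble_triplets(counts, meta, kept)
    report["n_presentations_kept"] = len(kept)


def stage_screen(cfg: RunConfig, state, out: Path, report) -> None:
    trips: list[Triplet] = state["triplets"]
    screen = screen_dataset(trips, seed=cfg.seed,
                            gof_threshold=cfg.gof_p_threshold,
                            bf_threshold=cfg.separation_bf_threshold)
    screen.to_csv(out / "screen.csv", index=False)
    state["screen"] = screen
    state["passed"] = [t for t, ok in zip(trips, screen["passed"]) if ok]
    report["n_triplets"] = len(trips)
    report["n_screened"] = len(state["passed"])


def stage_classify(cfg: RunConfig, state, out: Path, report) -> None:
    quad = cfg.quad_config()
    rows, scores = [], []
    state["classes"] = {}
    state["scores"] = {}
    state["win_probs"] = {}
    for t in state["passed"]:
        an = classify_triplet(t, quad=quad, require_screened=False)
        p = an.posterior
        key = (t.unit_id, t.condition_key)
        state["classes"][key] = p.winner
        state["scores"][key] = an.scores
        state["win_probs"][key] = p.win_prob if p.winner == "mixture" else 0.0
        rows.append({"unit_id": t.unit_id, "condition_key": t.condition_key,
                     "p_single": p.p_single, "p_outside": p.p_outside,
                     "p_intermediate": p.p_intermediate, "p_mixture": p.p_mixture,
                     "winner": p.winner, "win_prob": p.win_prob, "mc_se": p.mc_se,
                     "confident": p.confident, "majority": p.majority,
                     "alpha_mean": an.mixture.alpha_mean,
                     "alpha_lo": an.mixture.alpha_ci[0],
                     "alpha_hi": an.mixture.alpha_ci[1],
                     "seed": quad.seed, "config_hash": cfg.hash()})
        for j, s in enumerate(an.scores):
            scores.append({"unit_id": t.unit_id, "condition_key": t.condition_key,
                           "ab_index": j, "score": s})
    pd.DataFrame(rows).to_csv(out / "classification.csv", index=False)
    pd.DataFrame(scores).to_csv(out / "assignment_scores.csv", index=False)
    cls = pd.DataFrame(rows)
    if len(cls):
        confident = cls[cls["confident"]]
        report["winner_proportions_confident"] = (
            confident["winner"].value_counts(normalize=True).to_dict()
            if len(confident) else {})
        report["n_confident"] = int(len(confident))
        report["win_prob_confident_threshold"] = cfg.win_prob_confident


def stage_correlate(cfg: RunConfig, state, out: Path, report) -> None:
    rec = corr.build_pair_records(state["passed"], state["classes"],
                                  state["scores"], cfg.outlier_sd)
    rec.to_csv(out / "pair_records.csv", index=False)
    state["records"] = rec
    report["n_pair_records"] = len(rec)


def stage_summarize(cfg: RunConfig, state, out: Path, report) -> None:
    rec = state["records"]
    if rec.empty:
        report["medians"] = None
        return
    summ = corr.summarize_population(rec, n_shuffles=cfg.n_shuffles,
                                     seed=cfg.seed, driven_split=True)
    summ.to_csv(out / "medians.csv", index=False)
    tests = summ[["stimulus_set", "class_combo", "shuffle_p"]].dropna() \
        .drop_duplicates().to_dict("records")
    (out / "shuffle_tests.json").write_text(json.dumps(
        {"n_shuffles": cfg.n_shuffles, "seed": cfg.seed, "tests": tests},
        indent=2, default=_json_default))
    mm = summ[(summ.class_combo == "mixture|mixture") & (summ.stimulus_set == "AB")]
    report["mixture_pair_medians"] = {
        r["congruence"]: r["median_r_sc"] for _, r in mm.iterrows()}


def stage_popview(cfg: RunConfig, state, out: Path, report) -> None:
    keys = [k for k in state["scores"] if state["scores"][k] is not None]
    if not keys:
        report["popview"] = "no scored units"
        return
    key0 = keys[0][1]
    unit_scores = {u: state["scores"][(u, k)] for (u, k) in keys if k == key0}
    win = {u: state["win_probs"][(u, k)] for (u, k) in keys if k == key0}
    m = popview.build_trial_matrix(unit_scores, win, cfg.win_prob_majority)
    if m.empty:
        report["popview"] = "no unit passed mixture selection"
        return
    m.to_frame().to_csv(out / "trial_matrix.csv")
    per_trial, per_unit = popview.score_histograms(m)
    per_trial.to_csv(out / "hist_per_trial.csv")
    per_unit.to_csv(out / "hist_per_unit.csv")
    locked = popview.simulate_attention_locked(m, seed=cfg.seed)
    locked.to_frame().to_csv(out / "attention_locked.csv")
    avg = popview.simulate_averaging(len(m.unit_ids), len(m.trial_ids), seed=cfg.seed)
    avg.to_frame().to_csv(out / "averaging.csv")
    report["popview"] = {
        "n_units": len(m.unit_ids), "n_trials": len(m.trial_ids),
        "observed_mean_pairwise_r": popview.mean_pairwise_correlation(m),
        "attention_locked_mean_pairwise_r": popview.mean_pairwise_correlation(locked),
        "averaging_mean_pairwise_r": popview.mean_pairwise_correlation(avg)}


STAGE_FUNCS = {"simulate": stage_simulate, "ingest": stage_ingest,
               "screen": stage_screen, "classify": stage_classify,
               "correlate": stage_correlate, "summarize": stage_summarize,
               "popview": stage_popview}
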