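"""Validation studies of the statistical machinery (reduced problem sizes).

Runs the oracle-equivalence check of the marginal likelihoods, classifier
regime recovery, goodness-of-fit and shuffle-test calibration, the
coordinated-correlation recovery, the population-view comparators, and the
microsaccade detector's operating point, and writes a summary table.  The
test suite runs the same studies at full scale; this script uses smaller
replicate counts so it finishes in about a minute.
"""

import json
from pathlib import Path

from spikemux import experiments as ex

OUTDIR = Path(__file__).resolve().parent.parent / "results" / "validation"
SEED = 0


def main() -> None:
    OUTDIR.mkdir(parents=True, exist_ok=True)
    out = {}

    oracle = ex.oracle_comparison(n_instances=8, seed=SEED)
    out["oracle_max_abs_log_error"] = float(
        oracle[[c for c in oracle.columns if c.startswith("err_")]].to_numpy().max())

    rec = ex.classifier_recovery(n_triplets=120, seed=SEED)
    out["regime_recovery"] = {k: v["recovery"] for k, v in rec.items()}
    out["gof_exclusion_poisson"] = ex.gof_calibration(n_rep=300, seed=SEED)["exclusion_rate"]
    out["gof_exclusion_overdispersed"] = ex.gof_calibration(
        n_rep=300, dispersion=2.0, seed=SEED)["exclusion_rate"]
    out["shuffle_type_i"] = ex.shuffle_calibration(n_rep=300, seed=SEED)["type_i_rate"]
    out["correlation_structure"] = ex.correlation_structure(0.95, seed=SEED,
                                                            n_shuffles=2000)
    out["popview"] = ex.popview_comparators(seed=SEED)
    out["microsaccades"] = ex.microsaccade_detection(seed=SEED)
    out["alpha_recovery"] = ex.alpha_recovery(n_triplets=60, seed=SEED)

    (OUTDIR / "validation.json").write_text(json.dumps(out, indent=2, default=float))
    for k, v in out.items():
        print(f"{k}: {v}")


if __name__ == "__main__":
    main()
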