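"""Simulate the extreme-outlier discovery cohort.

Generates the default two-group bulk cohort (7 poor-outcome vs 6
good-outcome samples, 2000 genes with 100+100 planted programme genes),
its survival table, and writes small summaries under results/.  The full
expression matrix goes to scratch/ (regenerable from the seed).
"""

from pathlib import Path

import pandas as pd

from rplsig import io
from rplsig.synthio import SyntheticCohortConfig, generate_bulk_cohort, generate_survival

SEED = 2026
ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cfg = SyntheticCohortConfig(seed=SEED)
    expr, ann, truth = generate_bulk_cohort(cfg)
    surv = generate_survival(truth, baseline_hazard=0.05, censor_time=36.0, seed=SEED)

    scratch = ROOT / "scratch" / "simulated"
    scratch.mkdir(parents=True, exist_ok=True)
    io.write_expression(expr, scratch / "expression.tsv")
    io.write_annotations(ann, scratch / "annotations.tsv")
    io.write_json(truth.to_json_dict(), scratch / "truth.json")
    io.write_survival(surv, scratch / "survival.tsv")

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    summary = pd.DataFrame(
        {
            "n_samples": [expr.n_samples],
            "n_genes": [expr.n_genes],
            "n_group_a": [(ann["group"] == "A").sum()],
            "n_group_b": [(ann["group"] == "B").sum()],
            "n_planted_rp": [len(truth.arm_genes("rp_high"))],
            "n_planted_ls": [len(truth.arm_genes("ls_high"))],
            "events": [int(surv["event"].sum())],
            "censored": [int((1 - surv["event"]).sum())],
            "seed": [SEED],
        }
    )
    summary.to_csv(results / "01_cohort_summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))
    print(f"\ncohort written to {scratch}")


if __name__ == "__main__":
    main()
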