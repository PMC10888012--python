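"""Benchmark ΔΔG and RSA as threshold classifiers of pathogenicity.

For each score: ROC/AUC over the curated cohort, an MCC scan for the
operating cutoff, then the balanced-resampling report (100 repetitions of
equal-class draws) of TPR/FPR/FNR/accuracy at that cutoff.
"""

import sys
from pathlib import Path

from stabpath.evaluation import (
    DDG_GRID,
    RSA_GRID,
    MethodSpec,
    ScoredLabel,
    compare_methods,
    roc_curve,
)
from stabpath.stability_metrics import ensemble_average
from stabpath.variant_model import read_variant_table

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 20260921


def ddg_scorer(predictors):
    return lambda recs: [ensemble_average(r, predictors) for r in recs]


def main() -> None:
    records = read_variant_table(OUT / "curated_dataset1.tsv")

    methods = [
        MethodSpec("pred_a", ddg_scorer(("pred_a",))),
        MethodSpec("pred_b", ddg_scorer(("pred_b",))),
        MethodSpec("pred_weak", ddg_scorer(("pred_weak",))),
        MethodSpec("avg(pred_a,pred_b)", ddg_scorer(("pred_a", "pred_b"))),
        MethodSpec("rsa", lambda recs: [r.rsa for r in recs],
                   cutoff=0.35, grid=RSA_GRID),
    ]
    report = compare_methods(records, methods, n_reps=100, seed=SEED)
    report.to_csv(OUT / "threshold_benchmark.tsv", sep="\t", index=False)

    print("AUC per score:")
    for spec in methods:
        data = [ScoredLabel(float(s), r.label)
                for s, r in zip(spec.scorer(records), records)]
        print(f"  {spec.name:22s} {roc_curve(data).auc:.3f}")
    cols = ["method", "cutoff", "avg_tpr", "avg_fpr", "avg_fnr", "avg_accuracy"]
    print("\nbalanced-resampling benchmark (100 reps):")
    print(report[cols].round(3).to_string(index=False))
    return 0


if __name__ == "__main__":
    sys.exit(main())
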