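"""Train the logistic (ΔΔG, RSA) pathogenicity models.

One model per predictor ensemble, always with RSA: balance classes, split
80/20, select the regularization strength by 100× stratified 5-fold
cross-validation on held-out AUC, refit, and report AUC and MCC on both
splits.
"""

import json
import sys
from pathlib import Path

import pandas as pd

from stabpath.classifier import FeatureSpec, train_full_protocol
from stabpath.variant_model import read_variant_table

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 20260921

SPECS = [
    FeatureSpec("pred_a+rsa", ("pred_a",)),
    FeatureSpec("pred_b+rsa", ("pred_b",)),
    FeatureSpec("pred_weak+rsa", ("pred_weak",)),
    FeatureSpec("avg(pred_a,pred_b)+rsa", ("pred_a", "pred_b")),
    FeatureSpec("avg(all)+rsa", ("pred_a", "pred_b", "pred_weak")),
]


def main() -> None:
    records = read_variant_table(OUT / "curated_dataset1.tsv")
    rows, models = [], {}
    for spec in SPECS:
        model, train_m, test_m, cv = train_full_protocol(
            records, spec, seed=SEED, cv_reps=100
        )
        models[spec.name] = model.to_dict() | {"selected_c": cv.selected_c}
        rows.append(
            {
                "model": spec.name,
                "selected_c": cv.selected_c,
                "train_auc": train_m["auc"],
                "train_mcc": train_m["mcc"],
                "test_auc": test_m["auc"],
                "test_mcc": test_m["mcc"],
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "logistic_models.tsv", sep="\t", index=False)
    with open(OUT / "logistic_models.json", "w") as fh:
        json.dump(models, fh, indent=1)

    print("logistic models (AUC / MCC at probability cutoff 0.5):")
    print(table.round(3).to_string(index=False))
    best = table.loc[table["test_auc"].idxmax()]
    print(f"\nbest test AUC: {best['model']} "
          f"({best['test_auc']:.3f}, MCC {best['test_mcc']:.3f})")
    return 0


if __name__ == "__main__":
    sys.exit(main())
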