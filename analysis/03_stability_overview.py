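"""Stability census and substitution-category overview of the curated cohort.

Answers two descriptive questions: how destabilizing are the variants under
each predictor and cutoff (the stabilizing/destabilizing census), and how do
benign/pathogenic counts distribute over the chemical-property substitution
categories (hydropathy, size, ring, charge).
"""

import sys
from pathlib import Path

import pandas as pd

from stabpath.stability_metrics import (
    ensemble_average,
    fraction_destabilizing,
    stability_census,
)
from stabpath.variant_model import (
    count_by_category,
    filter_by_min_count,
    read_variant_table,
)

OUT = Path(__file__).resolve().parent.parent / "results"
SCORES = {
    "pred_a": ("pred_a",),
    "pred_b": ("pred_b",),
    "pred_weak": ("pred_weak",),
    "avg(pred_a,pred_b)": ("pred_a", "pred_b"),
    "avg(all)": ("pred_a", "pred_b", "pred_weak"),
}


def main() -> None:
    records = read_variant_table(OUT / "curated_dataset1.tsv")

    rows = []
    for name, predictors in SCORES.items():
        values = [ensemble_average(r, predictors) for r in records]
        for cutoff in (1.0, 1.1, 2.0):
            census = stability_census(values, cutoff)
            rows.append(
                {
                    "score": name,
                    "cutoff": cutoff,
                    "n_stabilizing": census.n_stabilizing,
                    "n_destabilizing": census.n_destabilizing,
                }
            )
    census_table = pd.DataFrame(rows)
    census_table.to_csv(OUT / "stability_census.tsv", sep="\t", index=False)

    pathogenic = [r for r in records if r.label == "pathogenic"]
    frac = fraction_destabilizing(pathogenic, ("pred_a", "pred_b"))
    print(f"{100 * frac:.1f}% of pathogenic variants have ensemble ΔΔG < 0 "
          f"(n={len(pathogenic)})")
    print("census (destabilizing ≫ stabilizing at every cutoff):")
    print(census_table.to_string(index=False))

    categories = filter_by_min_count(count_by_category(records), min_total=100)
    categories.to_csv(OUT / "substitution_categories.tsv", sep="\t", index=False)
    print(f"\n{len(categories)} substitution categories with >100 records "
          f"-> {OUT / 'substitution_categories.tsv'}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
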