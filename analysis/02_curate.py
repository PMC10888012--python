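"""Curate the cohort under both label policies.

Dataset 1 keeps only definite benign/pathogenic records; dataset 2 folds
the likely_* records into their parent class.  Reports how many records
each filter removed and writes the curated tables.
"""

import json
import sys
from pathlib import Path

from stabpath.curation import CurationConfig, curate
from stabpath.variant_model import read_variant_table, write_variant_table

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    records = read_variant_table(OUT / "cohort.tsv")
    for ds, include_likely in (("dataset1", False), ("dataset2", True)):
        kept, report = curate(records, CurationConfig(include_likely=include_likely))
        write_variant_table(kept, OUT / f"curated_{ds}.tsv")
        with open(OUT / f"curation_report_{ds}.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=1)
        d = report.to_dict()
        print(
            f"{ds}: kept {d['n_output']}/{d['n_input']} "
            f"(label -{d['n_dropped_label']}, frequency -{d['n_dropped_frequency']}, "
            f"conflict -{d['n_dropped_conflict']}, "
            f"gene balance -{d['n_dropped_gene_balance']})"
        )
    return 0


if __name__ == "__main__":
    sys.exit(main())
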