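"""Saturation-mutagenesis profile of the simulated proteins.

Enumerates all 19·L substitutions per protein, calls pathogenicity from the
oracle ΔΔG table at the −1.1 kcal/mol cutoff, and summarizes the pathogenic
fraction across the small proteome.
"""

import json
import sys
from pathlib import Path

import pandas as pd

from stabpath.saturation_profiler import (
    call_pathogenic,
    profile_to_frame,
    proteome_summary,
    read_ddg_table,
    read_fasta_sequences,
)

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    sequences = read_fasta_sequences(OUT / "proteins.fa")
    tables = read_ddg_table(OUT / "saturation_ddg.tsv")
    profiles = []
    for pid, seq in sequences.items():
        profile = call_pathogenic(seq, tables[pid], protein_id=pid)
        profiles.append(profile)
        print(f"{pid}: L={profile.length}, {profile.n_total} substitutions, "
              f"{profile.n_pathogenic} called pathogenic "
              f"({100 * profile.n_pathogenic / profile.n_total:.1f}%)")
    pd.concat([profile_to_frame(p) for p in profiles]).to_csv(
        OUT / "saturation_profile.tsv", sep="\t", index=False
    )
    summary = proteome_summary(profiles)
    with open(OUT / "saturation_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    print(f"proteome: {summary['n_pathogenic']}/{summary['n_total']} "
          f"({100 * summary['fraction']:.1f}%) potentially pathogenic "
          f"at ΔΔG ≤ -1.1 kcal/mol")
    return 0


if __name__ == "__main__":
    sys.exit(main())
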