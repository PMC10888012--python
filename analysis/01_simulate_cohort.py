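"""Generate the synthetic variant cohort the downstream analyses run on.

Writes a 3,000 + 3,000 record variant table (with planted curation
violations, three noisy ΔΔG predictor columns in their native sign
conventions, and RSA), the ground-truth sidecar, and a small FASTA +
ΔΔG-oracle pair for the saturation profiler.
"""

import sys
from pathlib import Path

from stabpath import synthetic_data as sd
from stabpath.variant_model import write_variant_table

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 20260921


def main() -> None:
    OUT.mkdir(exist_ok=True)
    config = sd.paper_shaped_config(n_benign=3000, n_pathogenic=3000)
    records, sidecar = sd.generate_variant_table(config, seed=SEED)
    write_variant_table(records, OUT / "cohort.tsv")
    sd.write_sidecar(sidecar, OUT / "cohort.truth.json")

    seqs, tables = {}, []
    for i, length in enumerate((400, 300, 300)):
        pid = f"prot{i + 1}"
        seq, ddg = sd.generate_saturation_oracle(
            length, pathogenic_mass=0.37, seed=SEED + 10 + i
        )
        seqs[pid] = seq
        for (pos, mut), v in ddg.items():
            tables.append(f"{pid}\t{pos}\t{seq[pos - 1]}\t{mut}\t{v!r}")
    sd.write_fasta(seqs, OUT / "proteins.fa")
    (OUT / "saturation_ddg.tsv").write_text(
        "protein_id\tposition\twt\tmut\tddg\n" + "\n".join(tables) + "\n"
    )

    n_path = sum(r.label.endswith("pathogenic") for r in records)
    print(f"cohort: {len(records)} records ({n_path} pathogenic-side), "
          f"{config.n_genes} balanced genes -> {OUT / 'cohort.tsv'}")
    print(f"saturation oracle: {len(seqs)} proteins, "
          f"{sum(len(s) for s in seqs.values()) * 19} substitutions")
    return 0


if __name__ == "__main__":
    sys.exit(main())
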