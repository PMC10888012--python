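"""In-silico saturation mutagenesis profiling.

Enumerates every substitution of a protein sequence to the 19 alternative
residues and calls each one pathogenic when its supplied ΔΔG (negative =
destabilizing) falls at or below a destabilization cutoff, −1.1 kcal/mol by
default.  ΔΔG values come from an external predictor table or a synthetic
oracle — this module never computes them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .variant_model import CANONICAL_RESIDUES, ValidationError

__all__ = [
    "DEFAULT_CUTOFF",
    "SaturationProfile",
    "enumerate_mutations",
    "call_pathogenic",
    "proteome_summary",
    "read_fasta_sequences",
    "read_ddg_table",
]

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = -1.1  # kcal/mol

_RESIDUES_SORTED = sorted(CANONICAL_RESIDUES)


@dataclass(frozen=True)
class SaturationProfile:
    protein_id: str
    length: int
    entries: tuple  # (position, wt, mut, ddg or None, pathogenic or None)
    skipped_positions: tuple[int, ...] = ()

    @property
    def n_total(self) -> int:
        """Number of entries with a ΔΔG call."""
        return sum(1 for e in self.entries if e[4] is not None)

    @property
    def n_pathogenic(self) -> int:
        return sum(1 for e in self.entries if e[4])

    @property
    def n_uncalled(self) -> int:
        return sum(1 for e in self.entries if e[4] is None)


def enumerate_mutations(
    sequence: str, protein_id: str = "protein"
) -> tuple[list[tuple[int, str, str]], list[int]]:
    """All 19 substitutions per canonical position, ordered by position then
    mutant residue alphabetically.

    Positions with a non-canonical wild-type residue are skipped with a
    warning.  Returns (substitutions, skipped positions).
    """
    if not sequence:
        raise ValidationError("empty sequence")
    subs: list[tuple[int, str, str]] = []
    skipped: list[int] = []
    for pos, wt in enumerate(str(sequence).upper(), start=1):
        if wt not in CANONICAL_RESIDUES:
            logger.warning(
                "%s: skipping non-canonical residue %r at position %d",
                protein_id, wt, pos,
            )
            skipped.append(pos)
            continue
        for mut in _RESIDUES_SORTED:
            if mut != wt:
                subs.append((pos, wt, mut))
    return subs, skipped


def call_pathogenic(
    sequence: str,
    ddg: Mapping[tuple[int, str], float],
    cutoff: float = DEFAULT_CUTOFF,
    protein_id: str = "protein",
) -> SaturationProfile:
    """Call every enumerated substitution pathogenic iff ΔΔG <= cutoff.

    ``ddg`` maps (position, mutant residue) to the predicted ΔΔG; entries
    without a value are kept but flagged uncalled and excluded from the
    called totals.
    """
    subs, skipped = enumerate_mutations(sequence, protein_id)
    entries = []
    for pos, wt, mut in subs:
        value = ddg.get((pos, mut))
        if value is None:
            entries.append((pos, wt, mut, None, None))
        else:
            entries.append((pos, wt, mut, float(value), float(value) <= cutoff))
    return SaturationProfile(
        protein_id=protein_id,
        length=len(sequence),
        entries=tuple(entries),
        skipped_positions=tuple(skipped),
    )


def proteome_summary(profiles: Iterable[SaturationProfile]) -> dict:
    """Aggregate called/pathogenic counts over proteins."""
    profiles = list(profiles)
    if not profiles:
        raise ValidationError("need at least one profile")
    n_total = sum(p.n_total for p in profiles)
    n_path = sum(p.n_pathogenic for p in profiles)
    return {
        "n_proteins": len(profiles),
        "n_total": n_total,
        "n_pathogenic": n_path,
        "fraction": n_path / n_total if n_total else float("nan"),
    }


def read_fasta_sequences(path) -> dict[str, str]:
    """Protein sequences keyed by record id."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_ddg_table(path) -> dict[str, dict[tuple[int, str], float]]:
    """TSV of (protein_id, position, wt, mut, ddg) -> nested ΔΔG lookup."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    out: dict[str, dict[tuple[int, str], float]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.protein_id), {})[(int(row.position), str(row.mut))] = (
            float(row.ddg)
        )
    return out


def profile_to_frame(profile: SaturationProfile) -> pd.DataFrame:
    return pd.DataFrame(
        profile.entries,
        columns=["position", "wt", "mut", "ddg", "pathogenic"],
    ).assign(protein_id=profile.protein_id)
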