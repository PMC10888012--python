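"""Dataset curation for clinical variant tables.

Mirrors the construction of a curated monogenic-disorder benchmark from a
ClinVar-style dump: resolve the four clinical labels to a binary
benign/pathogenic call, drop records whose population frequency contradicts
the label, drop records with cross-source disagreement, and finally drop
whole genes whose surviving records are too one-sided to contribute signal.

Two label policies are supported: the strict policy drops likely_* records
("dataset 1"); the inclusive policy folds them into their parent class
("dataset 2").
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .variant_model import BINARY_LABELS, LABELS, ValidationError, VariantRecord

__all__ = [
    "CurationConfig",
    "CurationReport",
    "resolve_labels",
    "frequency_filter",
    "conflict_filter",
    "gene_balance_filter",
    "curate",
]


@dataclass(frozen=True)
class CurationConfig:
    """Thresholds of the curation filters.

    freq_low / freq_high: benign records rarer than ``freq_low`` and
    pathogenic records commoner than ``freq_high`` are dropped (strict
    inequalities; a frequency of exactly 0.01 survives both rules).
    gene_balance_min: both class fractions within a gene must strictly exceed
    this for the gene to be kept.  include_likely selects the label policy.
    """

    freq_low: float = 0.01
    freq_high: float = 0.01
    gene_balance_min: float = 0.10
    include_likely: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.freq_low <= self.freq_high <= 1.0):
            raise ValidationError("require 0 <= freq_low <= freq_high <= 1")
        if not (0.0 <= self.gene_balance_min <= 0.5):
            raise ValidationError("gene_balance_min must be in [0, 0.5]")


@dataclass
class CurationReport:
    n_input: int = 0
    n_dropped_label: int = 0
    n_dropped_frequency: int = 0
    n_dropped_conflict: int = 0
    n_dropped_gene_balance: int = 0
    n_output: int = 0
    gene_status: dict[str, str] = field(default_factory=dict)

    def reconciles(self) -> bool:
        drops = (
            self.n_dropped_label
            + self.n_dropped_frequency
            + self.n_dropped_conflict
            + self.n_dropped_gene_balance
        )
        return self.n_input == self.n_output + drops

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_dropped_label": self.n_dropped_label,
            "n_dropped_frequency": self.n_dropped_frequency,
            "n_dropped_conflict": self.n_dropped_conflict,
            "n_dropped_gene_balance": self.n_dropped_gene_balance,
            "n_output": self.n_output,
            "gene_status": dict(sorted(self.gene_status.items())),
        }


_LIKELY = {"likely_benign": "benign", "likely_pathogenic": "pathogenic"}


def resolve_labels(
    records: list[VariantRecord], include_likely: bool
) -> tuple[list[VariantRecord], int]:
    """Resolve four-class labels to binary; returns (records, dropped count)."""
    out, dropped = [], 0
    for rec in records:
        if rec.label not in LABELS:
            raise ValidationError(f"unknown label {rec.label!r}")
        if rec.label in BINARY_LABELS:
            out.append(rec)
        elif include_likely:
            out.append(rec.with_label(_LIKELY[rec.label]))
        else:
            dropped += 1
    return out, dropped


def frequency_filter(
    records: list[VariantRecord], config: CurationConfig
) -> tuple[list[VariantRecord], int]:
    """Drop benign records rarer than freq_low and pathogenic ones commoner
    than freq_high; records without a frequency are retained."""
    out, dropped = [], 0
    for rec in records:
        f = rec.population_frequency
        if f is None:
            out.append(rec)
            continue
        if rec.label == "benign" and f < config.freq_low:
            dropped += 1
        elif rec.label == "pathogenic" and f > config.freq_high:
            dropped += 1
        else:
            out.append(rec)
    return out, dropped


def conflict_filter(records: list[VariantRecord]) -> tuple[list[VariantRecord], int]:
    """Drop records flagged as conflicting across sources."""
    out = [rec for rec in records if not rec.conflict]
    return out, len(records) - len(out)


def gene_balance_filter(
    records: list[VariantRecord], config: CurationConfig
) -> tuple[list[VariantRecord], int, dict[str, str]]:
    """Keep a gene iff both class fractions strictly exceed gene_balance_min.

    The fraction of exactly gene_balance_min fails (strict '>'); genes with a
    single class always fail.  Returns (records, dropped count, gene status).
    """
    by_gene: dict[str, list[VariantRecord]] = {}
    for rec in records:
        by_gene.setdefault(rec.gene_id, []).append(rec)
    status: dict[str, str] = {}
    out, dropped = [], 0
    for gene, recs in by_gene.items():
        n = len(recs)
        n_benign = sum(r.label == "benign" for r in recs)
        frac_b = n_benign / n
        frac_p = (n - n_benign) / n
        keep = frac_b > config.gene_balance_min and frac_p > config.gene_balance_min
        status[gene] = "kept" if keep else "dropped"
        if keep:
            out.extend(recs)
        else:
            dropped += n
    # preserve input order
    out_ids = {id(r) for r in out}
    ordered = [r for r in records if id(r) in out_ids]
    return ordered, dropped, status


def curate(
    records: list[VariantRecord], config: CurationConfig | None = None
) -> tuple[list[VariantRecord], CurationReport]:
    """Full curation pipeline.

    Stage order is fixed: label resolution, frequency filter, conflict filter,
    gene balance (balance computed on the survivors of the earlier stages).
    Each dropped record lands in exactly one report bucket.
    """
    config = config or CurationConfig()
    report = CurationReport(n_input=len(records))
    records, report.n_dropped_label = resolve_labels(records, config.include_likely)
    records, report.n_dropped_frequency = frequency_filter(records, config)
    records, report.n_dropped_conflict = conflict_filter(records)
    records, report.n_dropped_gene_balance, report.gene_status = gene_balance_filter(
        records, config
    )
    report.n_output = len(records)
    assert report.reconciles()
    return records, report
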