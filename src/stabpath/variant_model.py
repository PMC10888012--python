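"""Core variant data model and amino-acid property categorization.

Missense substitutions are categorized on four independent chemical-property
axes (hydropathy, size, ring character, charge).  A substitution is described
by the directed pair of group memberships on each axis for which *both*
residues belong to a named group; axes where one side falls outside the named
groups ("neither" ring character, "neutral" charge) simply do not contribute.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "CANONICAL_RESIDUES",
    "PROPERTY_GROUPS",
    "SubstitutionCategory",
    "VariantRecord",
    "ValidationError",
    "validate_residue",
    "residue_groups",
    "classify_substitution",
    "count_by_category",
    "filter_by_min_count",
    "read_variant_table",
    "write_variant_table",
]


class ValidationError(ValueError):
    """Raised when an input violates a structural precondition."""


CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

# Group definitions on the four property axes.  Hydropathy and size partition
# the 20 canonical residues; ring and charge leave remainders ("neither" /
# "neutral") that never form categories.  Lys sits in the aliphatic group in
# this scheme.
HYDROPHOBIC = frozenset("ACGILMFPWV")
POLAR = CANONICAL_RESIDUES - HYDROPHOBIC
SMALL = frozenset("ACGSNDPTV")
LARGE = CANONICAL_RESIDUES - SMALL
AROMATIC = frozenset("HFWY")
ALIPHATIC = frozenset("AIKLMPV")
POSITIVE = frozenset("HKR")
NEGATIVE = frozenset("DE")

#: axis name -> {group name -> residue set}
PROPERTY_GROUPS: Mapping[str, Mapping[str, frozenset]] = {
    "hydropathy": {"hydrophobic": HYDROPHOBIC, "polar": POLAR},
    "size": {"small": SMALL, "large": LARGE},
    "ring": {"aromatic": AROMATIC, "aliphatic": ALIPHATIC},
    "charge": {"positive": POSITIVE, "negative": NEGATIVE},
}

AXES = tuple(PROPERTY_GROUPS)

LABELS = ("benign", "likely_benign", "pathogenic", "likely_pathogenic")
BINARY_LABELS = ("benign", "pathogenic")


def validate_residue(code: str) -> str:
    """Return the upper-case one-letter code, rejecting non-canonical residues."""
    if not isinstance(code, str) or len(code) != 1:
        raise ValidationError(f"residue must be a one-letter code, got {code!r}")
    up = code.upper()
    if up not in CANONICAL_RESIDUES:
        raise ValidationError(f"non-canonical residue {code!r}")
    return up


def residue_groups(code: str) -> dict[str, str | None]:
    """Group membership of one residue on each axis (None where unnamed)."""
    code = validate_residue(code)
    out: dict[str, str | None] = {}
    for axis, groups in PROPERTY_GROUPS.items():
        out[axis] = next((g for g, members in groups.items() if code in members), None)
    return out


@dataclass(frozen=True, order=True)
class SubstitutionCategory:
    """A directed (from-group, to-group) pair on one property axis."""

    axis: str
    from_group: str
    to_group: str

    def __post_init__(self) -> None:
        groups = PROPERTY_GROUPS.get(self.axis)
        if groups is None:
            raise ValidationError(f"unknown axis {self.axis!r}")
        for g in (self.from_group, self.to_group):
            if g not in groups:
                raise ValidationError(f"{g!r} is not a group of axis {self.axis!r}")

    def __str__(self) -> str:  # e.g. "hydrophobic-polar"
        return f"{self.from_group}-{self.to_group}"


@dataclass(frozen=True)
class VariantRecord:
    """One missense variant with clinical label and predictor read-outs.

    ``ddg`` maps predictor name to ΔΔG in kcal/mol, already normalized to the
    convention in which negative values destabilize. ``position`` is the
    1-based residue index (mutation notation, e.g. C163S).
    """

    gene_id: str
    protein_id: str
    position: int
    wt: str
    mut: str
    label: str
    population_frequency: float | None = None
    conflict: bool = False
    ddg: Mapping[str, float] = field(default_factory=dict)
    rsa: float | None = None
    functional_category: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "wt", validate_residue(self.wt))
        object.__setattr__(self, "mut", validate_residue(self.mut))
        if self.wt == self.mut:
            raise ValidationError(f"not a missense substitution: {self.wt}->{self.mut}")
        if self.label not in LABELS:
            raise ValidationError(f"unknown clinical label {self.label!r}")
        if self.position < 1:
            raise ValidationError("position is 1-based and must be >= 1")
        if self.population_frequency is not None and not (
            0.0 <= self.population_frequency <= 1.0
        ):
            raise ValidationError(
                f"population frequency {self.population_frequency} outside [0, 1]"
            )
        if self.rsa is not None and not (0.0 <= self.rsa <= 1.0):
            raise ValidationError(f"RSA {self.rsa} outside [0, 1]")

    def with_label(self, label: str) -> "VariantRecord":
        return replace(self, label=label)


def classify_substitution(wt: str, mut: str) -> set[SubstitutionCategory]:
    """Directed property categories of a substitution, one per applicable axis.

    Hydropathy and size always contribute (they partition the residues); ring
    and charge contribute only when both residues have a named group there.
    """
    wt, mut = validate_residue(wt), validate_residue(mut)
    if wt == mut:
        raise ValidationError("wt and mut must differ")
    wt_groups = residue_groups(wt)
    mut_groups = residue_groups(mut)
    out = set()
    for axis in AXES:
        fg, tg = wt_groups[axis], mut_groups[axis]
        if fg is not None and tg is not None:
            out.add(SubstitutionCategory(axis, fg, tg))
    return out


def count_by_category(records: Iterable[VariantRecord]) -> pd.DataFrame:
    """Per-category benign/pathogenic counts.

    A record contributes to every category its substitution belongs to.
    Records must carry binary labels (run curation first).  Returns a frame
    with columns axis, from_group, to_group, n_benign, n_pathogenic.
    """
    counts: dict[SubstitutionCategory, dict[str, int]] = {}
    for rec in records:
        if rec.label not in BINARY_LABELS:
            raise ValidationError(
                f"count_by_category requires binary labels, got {rec.label!r}"
            )
        for cat in classify_substitution(rec.wt, rec.mut):
            row = counts.setdefault(cat, {"benign": 0, "pathogenic": 0})
            row[rec.label] += 1
    rows = [
        {
            "axis": cat.axis,
            "from_group": cat.from_group,
            "to_group": cat.to_group,
            "n_benign": row["benign"],
            "n_pathogenic": row["pathogenic"],
        }
        for cat, row in sorted(counts.items())
    ]
    return pd.DataFrame(
        rows, columns=["axis", "from_group", "to_group", "n_benign", "n_pathogenic"]
    )


def filter_by_min_count(table: pd.DataFrame, min_total: int = 100) -> pd.DataFrame:
    """Keep only categories whose total count strictly exceeds ``min_total``."""
    if table.empty:
        return table.copy()
    total = table["n_benign"] + table["n_pathogenic"]
    return table.loc[total > min_total].reset_index(drop=True)


# ---------------------------------------------------------------------------
# TSV interface

_MISSING = {"", "."}


def _parse_optional_float(value) -> float | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    if s in _MISSING:
        return None
    return float(s)


def _parse_bool(value) -> bool:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return False
    s = str(value).strip().lower()
    if s in _MISSING:
        return False
    if s in {"true", "1", "yes"}:
        return True
    if s in {"false", "0", "no"}:
        return False
    raise ValidationError(f"cannot interpret conflict flag {value!r}")


def read_variant_table(path) -> list[VariantRecord]:
    """Read the tab-separated variant table ("." or empty cell = missing).

    Required columns: gene_id, protein_id, position, wt, mut, label.
    Optional: population_frequency, conflict, rsa, functional_category and any
    number of ``ddg_<predictor>`` columns.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["gene_id", "protein_id", "position", "wt", "mut", "label"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"variant table missing columns: {missing}")
    ddg_cols = [c for c in df.columns if c.startswith("ddg_")]
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        ddg = {}
        for col in ddg_cols:
            v = _parse_optional_float(d[col])
            if v is not None:
                ddg[col[len("ddg_") :]] = v
        records.append(
            VariantRecord(
                gene_id=d["gene_id"],
                protein_id=d["protein_id"],
                position=int(d["position"]),
                wt=d["wt"],
                mut=d["mut"],
                label=d["label"],
                population_frequency=_parse_optional_float(
                    d.get("population_frequency")
                ),
                conflict=_parse_bool(d.get("conflict")),
                ddg=ddg,
                rsa=_parse_optional_float(d.get("rsa")),
                functional_category=(
                    None
                    if d.get("functional_category") in (None, "", ".")
                    else d["functional_category"]
                ),
            )
        )
    return records


def write_variant_table(records: Iterable[VariantRecord], path) -> None:
    """Write records to TSV, missing values as '.'."""
    records = list(records)
    predictors = sorted({p for r in records for p in r.ddg})
    rows = []
    for r in records:
        row = {
            "gene_id": r.gene_id,
            "protein_id": r.protein_id,
            "position": r.position,
            "wt": r.wt,
            "mut": r.mut,
            "label": r.label,
            "population_frequency": (
                "." if r.population_frequency is None else repr(r.population_frequency)
            ),
            "conflict": str(r.conflict).lower(),
            "rsa": "." if r.rsa is None else repr(r.rsa),
            "functional_category": r.functional_category or ".",
        }
        for p in predictors:
            row[f"ddg_{p}"] = "." if p not in r.ddg else repr(r.ddg[p])
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
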