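"""Synthetic cohorts with the statistical structure of a curated
monogenic-disorder variant benchmark.

The generator emulates the joint behaviour the downstream analyses assume,
without modelling any real predictor:

* a latent "true" ΔΔG per variant, drawn from a class-conditional two-sided
  mixture calibrated so that a configured fraction of pathogenic variants
  (70% by default) is destabilizing (ΔΔG < 0), benign variants less so;
* several noisy predictor read-outs of that shared latent value, each with
  its own noise level and declared sign convention, which reproduces
  inter-predictor correlation and lets one predictor be made deliberately
  weak;
* RSA drawn from class-conditional Beta laws (pathogenic buried-skewed,
  mode below 0.35; benign exposed-skewed) coupled to the latent ΔΔG through
  a Gaussian copula with a small configured correlation — the two signals
  are informative individually and nearly independent;
* population frequencies, conflict flags, likely_* labels and one-sided
  genes planted at configured rates as curation-rule violations, with a
  ground-truth sidecar recording each record's latent ΔΔG and planted fate.

Everything is driven by a single integer seed and is byte-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .stability_metrics import SignConvention, normalize_sign
from .variant_model import (
    CANONICAL_RESIDUES,
    ValidationError,
    VariantRecord,
)

__all__ = [
    "ClassMixture",
    "PredictorSpec",
    "SyntheticConfig",
    "paper_shaped_config",
    "generate_variant_table",
    "generate_logistic_dataset",
    "generate_saturation_oracle",
    "random_protein_sequence",
    "write_fasta",
    "write_sidecar",
]

_RESIDUES = sorted(CANONICAL_RESIDUES)


@dataclass(frozen=True)
class ClassMixture:
    """Two-sided latent ΔΔG law: a destabilizing (negative, truncated-normal)
    and a stabilizing (positive) component with an exact destabilizing mass."""

    p_destabilizing: float
    neg_mean: float
    neg_sd: float
    pos_mean: float
    pos_sd: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_destabilizing <= 1.0):
            raise ValidationError("p_destabilizing must be in [0, 1]")
        if self.neg_sd <= 0 or self.pos_sd <= 0:
            raise ValidationError("mixture sds must be positive")

    def _components(self):
        neg = stats.truncnorm(
            a=-np.inf, b=(0.0 - self.neg_mean) / self.neg_sd,
            loc=self.neg_mean, scale=self.neg_sd,
        )
        pos = stats.truncnorm(
            a=(0.0 - self.pos_mean) / self.pos_sd, b=np.inf,
            loc=self.pos_mean, scale=self.pos_sd,
        )
        return neg, pos

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        neg, pos = self._components()
        destab = rng.random(n) < self.p_destabilizing
        out = np.empty(n)
        out[destab] = neg.rvs(int(destab.sum()), random_state=rng)
        out[~destab] = pos.rvs(int((~destab).sum()), random_state=rng)
        return out

    def cdf(self, g: np.ndarray) -> np.ndarray:
        neg, pos = self._components()
        return self.p_destabilizing * neg.cdf(g) + (
            1.0 - self.p_destabilizing
        ) * pos.cdf(g)


@dataclass(frozen=True)
class PredictorSpec:
    """One emulated ΔΔG predictor: read-out = latent + N(0, noise_sd),
    emitted in the declared sign convention."""

    name: str
    noise_sd: float
    negative_is_destabilizing: bool = True

    @property
    def convention(self) -> SignConvention:
        return SignConvention(self.name, self.negative_is_destabilizing)


@dataclass(frozen=True)
class SyntheticConfig:
    n_benign: int = 3000
    n_pathogenic: int = 3000
    n_genes: int = 40
    pathogenic_mixture: ClassMixture = field(
        default_factory=lambda: ClassMixture(0.70, -2.8, 1.6, 0.6, 0.5)
    )
    benign_mixture: ClassMixture = field(
        default_factory=lambda: ClassMixture(0.55, -0.4, 0.4, 0.4, 0.4)
    )
    predictors: tuple[PredictorSpec, ...] = (
        PredictorSpec("pred_a", noise_sd=0.8),
        PredictorSpec("pred_b", noise_sd=1.0),
        PredictorSpec("pred_weak", noise_sd=2.5, negative_is_destabilizing=False),
    )
    # RSA Beta(a, b) per class: pathogenic mode 0.25 (buried), benign 0.53
    rsa_pathogenic: tuple[float, float] = (2.0, 4.0)
    rsa_benign: tuple[float, float] = (2.6, 2.4)
    ddg_rsa_correlation: float = 0.1  # class-conditional Gaussian-copula coupling
    # planted curation-violation rates (per record, mutually exclusive fates)
    rate_likely: float = 0.10
    rate_frequency_violation: float = 0.05
    rate_conflict: float = 0.05
    rate_unbalanced_gene: float = 0.05
    frequency_missing_rate: float = 0.30
    max_position: int = 500

    def __post_init__(self) -> None:
        if self.n_benign <= 0 or self.n_pathogenic <= 0 or self.n_genes <= 0:
            raise ValidationError("counts must be positive")
        if abs(self.ddg_rsa_correlation) >= 0.3:
            raise ValidationError(
                "ΔΔG–RSA coupling must stay weak (|rho| < 0.3)"
            )
        rates = (
            self.rate_likely
            + self.rate_frequency_violation
            + self.rate_conflict
            + self.rate_unbalanced_gene
        )
        if rates >= 1.0:
            raise ValidationError("violation rates must sum below 1")


def paper_shaped_config(**overrides) -> SyntheticConfig:
    """The default study conditions (70% of pathogenic destabilizing, weak
    ΔΔG–RSA coupling, one deliberately weak predictor)."""
    return SyntheticConfig(**overrides)


_FATES = ("clean", "likely", "frequency", "conflict", "gene_unbalanced")


def _assign_fates(n: int, config: SyntheticConfig, rng) -> np.ndarray:
    p = np.array(
        [
            1.0
            - config.rate_likely
            - config.rate_frequency_violation
            - config.rate_conflict
            - config.rate_unbalanced_gene,
            config.rate_likely,
            config.rate_frequency_violation,
            config.rate_conflict,
            config.rate_unbalanced_gene,
        ]
    )
    return rng.choice(len(_FATES), size=n, p=p)


def _sample_class(
    n: int,
    mixture: ClassMixture,
    rsa_ab: tuple[float, float],
    rho: float,
    config: SyntheticConfig,
    rng: np.random.Generator,
):
    """Latent ΔΔG, RSA (copula-coupled), and per-predictor read-outs."""
    g = mixture.sample(n, rng)
    u = np.clip(mixture.cdf(g), 1e-12, 1 - 1e-12)
    z_g = stats.norm.ppf(u)
    z_rsa = rho * z_g + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)
    u_rsa = np.clip(stats.norm.cdf(z_rsa), 1e-12, 1 - 1e-12)
    rsa = stats.beta.ppf(u_rsa, *rsa_ab)
    preds = {
        spec.name: g + rng.normal(0.0, spec.noise_sd, size=n)
        for spec in config.predictors
    }
    return g, rsa, preds


def generate_variant_table(
    config: SyntheticConfig | None = None, seed: int = 0
) -> tuple[list[VariantRecord], list[dict]]:
    """A synthetic variant cohort plus its ground-truth sidecar.

    Records carry ΔΔG already normalized to the negative-destabilizing
    convention (each predictor's declared convention applies to its emitted
    table column, see ``emit_raw_frame``).  The sidecar holds, per record,
    the latent ΔΔG, the planted curation fate and the expected survival under
    the strict (dataset-1) and inclusive (dataset-2) label policies.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(seed)

    per_class = {
        "benign": (config.n_benign, config.benign_mixture, config.rsa_benign),
        "pathogenic": (
            config.n_pathogenic,
            config.pathogenic_mixture,
            config.rsa_pathogenic,
        ),
    }
    records: list[VariantRecord] = []
    sidecar: list[dict] = []
    balanced_genes = [f"GENE{i:03d}" for i in range(config.n_genes)]
    rr = {"benign": 0, "pathogenic": 0}  # round-robin cursors per class

    for cls, (n, mixture, rsa_ab) in per_class.items():
        g, rsa, preds = _sample_class(
            n, mixture, rsa_ab, config.ddg_rsa_correlation, config, rng
        )
        fates = _assign_fates(n, config, rng)
        n_clean = int(np.sum(fates == 0))
        if n_clean < config.n_genes:
            raise ValidationError(
                "infeasible config: fewer clean records than genes "
                f"({n_clean} < {config.n_genes}) for class {cls}"
            )
        for i in range(n):
            fate = _FATES[fates[i]]
            # gene assignment: survivors and recoverable records rotate over
            # the balanced genes (keeps every kept gene two-sided); records
            # planted for the gene-balance rule live in one-sided genes
            if fate == "gene_unbalanced":
                gene = f"UNBAL_{cls.upper()}"
            else:
                gene = balanced_genes[rr[cls] % config.n_genes]
                rr[cls] += 1
            label = cls
            if fate == "likely":
                label = f"likely_{cls}"
            # population frequency: benign are common, pathogenic rare;
            # the "frequency" fate plants the opposite (rule-violating) range
            freq: float | None
            if fate == "frequency":
                freq = (
                    rng.uniform(0.0, 0.0099)
                    if cls == "benign"
                    else rng.uniform(0.0101, 0.1)
                )
            elif rng.random() < config.frequency_missing_rate:
                freq = None
            else:
                freq = (
                    rng.uniform(0.01, 0.2)
                    if cls == "benign"
                    else rng.uniform(0.0, 0.01)
                )
            wt = _RESIDUES[rng.integers(20)]
            mut = [r for r in _RESIDUES if r != wt][rng.integers(19)]
            ddg = {
                spec.name: float(preds[spec.name][i])
                for spec in config.predictors
            }
            records.append(
                VariantRecord(
                    gene_id=gene,
                    protein_id=f"{gene}_P1",
                    position=int(rng.integers(1, config.max_position + 1)),
                    wt=wt,
                    mut=mut,
                    label=label,
                    population_frequency=freq,
                    conflict=(fate == "conflict"),
                    ddg=ddg,
                    rsa=float(rsa[i]),
                )
            )
            sidecar.append(
                {
                    "true_class": cls,
                    "latent_ddg": float(g[i]),
                    "destabilizing": bool(g[i] < 0),
                    "fate": fate,
                    "survives_dataset1": fate == "clean",
                    "survives_dataset2": fate in ("clean", "likely"),
                }
            )
    # interleave deterministically so classes are not block-ordered
    order = np.random.default_rng(seed + 1).permutation(len(records))
    records = [records[i] for i in order]
    sidecar = [sidecar[int(i)] | {"index": int(k)} for k, i in enumerate(order)]
    return records, sidecar


def emit_raw_frame(
    records: Sequence[VariantRecord], config: SyntheticConfig
) -> pd.DataFrame:
    """Variant table with each ΔΔG column flipped back into its predictor's
    declared sign convention (what an external tool would actually emit)."""
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
                "." if r.population_frequency is None else r.population_frequency
            ),
            "conflict": str(r.conflict).lower(),
            "rsa": r.rsa,
        }
        for spec in config.predictors:
            row[f"ddg_{spec.name}"] = normalize_sign(
                r.ddg[spec.name], spec.convention
            )  # involution: paper -> declared
        rows.append(row)
    return pd.DataFrame(rows)


def write_sidecar(sidecar: list[dict], path) -> None:
    with open(path, "w") as fh:
        json.dump(sidecar, fh, indent=1)


def generate_logistic_dataset(
    intercept: float,
    coefficients: Sequence[float],
    n: int,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Features ~ N(0,1) with Bernoulli labels from the exact logistic law."""
    if n < 100:
        raise ValidationError("n must be at least 100")
    rng = np.random.default_rng(seed)
    w = np.asarray(coefficients, dtype=float)
    X = rng.standard_normal((n, w.size))
    z = intercept + X @ w
    p = 1.0 / (1.0 + np.exp(-z))
    y = rng.random(n) < p
    return X, y, {"intercept": float(intercept), "coefficients": w.tolist()}


def random_protein_sequence(length: int, seed: int = 0) -> str:
    rng = np.random.default_rng(seed)
    return "".join(_RESIDUES[i] for i in rng.integers(0, 20, size=length))


def generate_saturation_oracle(
    sequence: str | int,
    pathogenic_mass: float = 0.37,
    cutoff: float = -1.1,
    seed: int = 0,
) -> tuple[str, dict[tuple[int, str], float]]:
    """ΔΔG oracle for all 19·L substitutions of a sequence.

    Each substitution falls at or below the cutoff with probability exactly
    ``pathogenic_mass`` (sub- and supra-threshold values are drawn from
    exponential tails hanging off the cutoff, so the mass is exact by
    truncation).  An integer argument generates a random sequence of that
    length first.
    """
    if not (0.0 <= pathogenic_mass <= 1.0):
        raise ValidationError("pathogenic_mass must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if isinstance(sequence, int):
        if sequence < 1:
            raise ValidationError("length must be >= 1")
        sequence = random_protein_sequence(sequence, seed=seed + 1)
    table: dict[tuple[int, str], float] = {}
    for pos, wt in enumerate(sequence, start=1):
        for mut in _RESIDUES:
            if mut == wt:
                continue
            if rng.random() < pathogenic_mass:
                value = cutoff - rng.exponential(1.0)
            else:
                value = cutoff + 1e-9 + rng.exponential(1.0)
            table[(pos, mut)] = float(value)
    return sequence, table


def write_fasta(sequences: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def config_to_dict(config: SyntheticConfig) -> dict:
    return asdict(config)
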