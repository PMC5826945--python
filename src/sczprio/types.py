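"""Core record types shared across pipeline stages.

Summary statistics live on the standardized z-score scale (unit standard
error), so a two-sided p-value and an absolute z-score are interchangeable:
p = 2*Phi(-|z|).  All integrative statistics downstream use z**2 only, so a
z recovered from a p-value with unknown sign is lossless for them; such
records carry ``sign_known=False``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .errors import ValidationError

#: Ordered names of the nine convergent-evidence channels.  The first six are
#: derived from in-pipeline results; the last three come from external
#: resources (brain imaging, cognition, functional assays) and are supplied
#: as per-gene booleans.
CFG_CHANNELS: tuple[str, ...] = (
    "sherlock_discovery",
    "ppi",
    "coexpression",
    "differential_expression",
    "sherlock_replication",
    "smr",
    "brain_structure",
    "cognition",
    "functional_assay",
)


def p_from_z(z):
    """Two-sided normal tail probability of |z|."""
    return 2.0 * _stats.norm.sf(np.abs(z))


def z_from_p(p):
    """Positive z whose two-sided normal tail probability equals p."""
    return _stats.norm.isf(np.asarray(p, dtype=float) / 2.0)


def _check_p(p: float, what: str) -> None:
    if not (0.0 < p <= 1.0) or not math.isfinite(p):
        raise ValidationError(f"{what}: p-value {p!r} outside (0, 1]")


@dataclass(frozen=True)
class SnpAssociation:
    """Per-SNP GWAS summary statistic (z and two-sided p)."""

    snp_id: str
    z_score: float
    p_value: float
    sign_known: bool = True

    def __post_init__(self):
        _check_p(self.p_value, self.snp_id)
        if not math.isfinite(self.z_score):
            raise ValidationError(f"{self.snp_id}: non-finite z-score")
        expected = float(p_from_z(self.z_score))
        if expected > 0 and abs(expected - self.p_value) > 1e-6 * expected:
            raise ValidationError(
                f"{self.snp_id}: p-value {self.p_value:g} inconsistent with "
                f"|z| = {abs(self.z_score):g} (expected p = {expected:g})"
            )


@dataclass(frozen=True)
class EqtlAssociation:
    """Per-(SNP, gene) eQTL summary statistic with a cis/trans flag."""

    snp_id: str
    gene_id: str
    z_score: float
    p_value: float
    cis_trans: str
    sign_known: bool = True

    def __post_init__(self):
        _check_p(self.p_value, f"{self.snp_id}/{self.gene_id}")
        if not math.isfinite(self.z_score):
            raise ValidationError(f"{self.snp_id}/{self.gene_id}: non-finite z")
        if self.cis_trans not in ("cis", "trans"):
            raise ValidationError(
                f"{self.snp_id}/{self.gene_id}: cis_trans must be 'cis' or "
                f"'trans', got {self.cis_trans!r}"
            )
        expected = float(p_from_z(self.z_score))
        if expected > 0 and abs(expected - self.p_value) > 1e-6 * expected:
            raise ValidationError(
                f"{self.snp_id}/{self.gene_id}: p inconsistent with |z|"
            )


@dataclass
class GeneLbfResult:
    """Gene-level log-Bayes-factor score accumulated over the gene's eSNPs.

    ``total_lbf`` is the sum of per-eSNP log Bayes factors (nats); the gene's
    empirical p-value comes from a Monte-Carlo null in which every eSNP draws
    a standard-normal GWAS z.
    """

    gene_id: str
    esnp_ids: list[str]
    esnp_lbfs: list[float]
    total_lbf: float
    top_esnp: str
    empirical_p: float | None = None
    corrected_p: float | None = None


@dataclass
class SmrResult:
    """Single-instrument summary-data Mendelian-randomization result."""

    gene_id: str
    instrument_snp: str
    z_gwas: float
    z_eqtl: float
    t_smr: float
    p_smr: float
    corrected_p: float | None = None


@dataclass(frozen=True)
class PermutationTestResult:
    """Outcome of a matched-random-gene-set permutation test.

    p_value is the exceedance fraction k/n; when k = 0 the test has hit its
    resolution floor and is reported as "< 1/n".
    """

    observed_statistic: float
    n_permutations: int
    n_exceeding: int
    seed: int | None = None
    draw_size: int | None = None

    @property
    def p_value(self) -> float:
        return self.n_exceeding / self.n_permutations

    @property
    def below_resolution(self) -> bool:
        return self.n_exceeding == 0

    @property
    def p_report(self) -> str:
        if self.below_resolution:
            return f"< {1.0 / self.n_permutations:g}"
        return f"{self.p_value:g}"


@dataclass
class DeResult:
    """Two-sample case/control differential-expression test for one gene in one region."""

    gene_id: str
    region: str
    mean_case: float
    mean_control: float
    t_statistic: float
    p_two_sided: float
    direction: str  # "up" or "down" in cases
    n_case: int
    n_control: int


@dataclass
class CfgEvidence:
    """Per-gene boolean evidence vector over the nine CFG channels."""

    gene_id: str
    channels: dict[str, bool]

    def __post_init__(self):
        if tuple(self.channels) != CFG_CHANNELS:
            raise ValidationError(
                "CFG evidence must carry exactly the nine named channels in order"
            )

    @property
    def score(self) -> int:
        return int(sum(self.channels.values()))


_META_COLUMNS = ("donor", "region", "age_days", "stage", "diagnosis")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression with per-sample metadata.

    ``values``: DataFrame indexed by gene id, columns are sample ids.
    ``meta``: DataFrame indexed by sample id with columns donor, region,
    age_days (post-conception days), stage, diagnosis ({case, control, NA}).
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self):
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValidationError(f"duplicate gene ids: {list(dups)[:5]}")
        missing = [c for c in _META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise ValidationError(f"metadata missing columns: {missing}")
        if set(self.values.columns) != set(self.meta.index):
            raise ValidationError("metadata samples do not match matrix columns")
        ages = pd.to_numeric(self.meta["age_days"], errors="coerce")
        if ages.isna().any() or (ages <= 0).any():
            raise ValidationError("sample ages must be positive numbers")
        # align metadata row order with matrix column order
        self.meta = self.meta.loc[list(self.values.columns)]

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def cluster_samples(self, cluster_map: dict[str, str], cluster: str) -> list[str]:
        """Sample ids whose region maps to the given cluster."""
        mask = self.meta["region"].map(cluster_map) == cluster
        return list(self.meta.index[mask])


@dataclass
class SyntheticTruth:
    """Ledger of signals planted by the synthetic-data generators."""

    risk_genes: list[str] = field(default_factory=list)
    de_genes: dict[str, float] = field(default_factory=dict)  # gene -> signed shift
    early_high_genes: list[str] = field(default_factory=list)
    coexpr_block_genes: list[str] = field(default_factory=list)
    enriched_candidate_set: list[str] = field(default_factory=list)
    seeds: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "risk_genes": sorted(self.risk_genes),
            "de_genes": {g: float(s) for g, s in sorted(self.de_genes.items())},
            "early_high_genes": sorted(self.early_high_genes),
            "coexpr_block_genes": sorted(self.coexpr_block_genes),
            "enriched_candidate_set": sorted(self.enriched_candidate_set),
            "seeds": {k: int(v) for k, v in sorted(self.seeds.items())},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticTruth":
        return cls(
            risk_genes=list(d.get("risk_genes", [])),
            de_genes={k: float(v) for k, v in d.get("de_genes", {}).items()},
            early_high_genes=list(d.get("early_high_genes", [])),
            coexpr_block_genes=list(d.get("coexpr_block_genes", [])),
            enriched_candidate_set=list(d.get("enriched_candidate_set", [])),
            seeds={k: int(v) for k, v in d.get("seeds", {}).items()},
        )

    def merged(self, other: "SyntheticTruth") -> "SyntheticTruth":
        return SyntheticTruth(
            risk_genes=sorted(set(self.risk_genes) | set(other.risk_genes)),
            de_genes={**self.de_genes, **other.de_genes},
            early_high_genes=sorted(
                set(self.early_high_genes) | set(other.early_high_genes)
            ),
            coexpr_block_genes=sorted(
                set(self.coexpr_block_genes) | set(other.coexpr_block_genes)
            ),
            enriched_candidate_set=sorted(
                set(self.enriched_candidate_set) | set(other.enriched_candidate_set)
            ),
            seeds={**self.seeds, **other.seeds},
        )
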