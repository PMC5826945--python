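"""Bayesian eQTL-GWAS gene scoring via summed per-eSNP log Bayes factors.

For each gene, the SNPs associated with its expression (eSNPs, eQTL p below
a threshold) are scored by an approximate Bayes factor comparing "the eSNP
is associated with disease" against the null, computed from the GWAS z-score
on the standardized scale (unit sampling variance) with a Normal(0, W) prior
on the true standardized effect:

    LBF(z; W) = 0.5 * ln(1 / (1 + W)) + (z^2 / 2) * (W / (1 + W))

The score is strictly increasing in z^2, negative at z = 0 (an eSNP with no
disease signal subtracts evidence), and crosses zero at
z^2 = ((1 + W) / W) * ln(1 + W).  The gene's score is the sum of its eSNP
LBFs; exp(total LBF) is the odds of association versus the null.  SNPs with
GWAS signal but no eQTL association never enter the score.

Gene-level significance uses a Monte-Carlo null: a matched null gene has the
same number of eSNPs, each drawing a standard-normal GWAS z; the empirical
p-value uses the add-one convention (1 + k) / (1 + n).
"""

from __future__ import annotations

import logging
import math
from typing import Mapping, Sequence

import numpy as np

from .config import PipelineConfig
from .errors import ParameterError, ValidationError
from .types import EqtlAssociation, GeneLbfResult, SnpAssociation

logger = logging.getLogger(__name__)


def esnp_lbf(gwas_z, prior_variance_w: float):
    """Log Bayes factor (nats) for one eSNP given its GWAS z-score.

    Accepts a scalar or array z.  Raises on non-finite z.
    """
    if prior_variance_w <= 0:
        raise ParameterError("prior_variance_w must be positive")
    z = np.asarray(gwas_z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValidationError("non-finite GWAS z-score")
    w = prior_variance_w
    shrink = w / (1.0 + w)
    out = -0.5 * math.log1p(w) + 0.5 * z * z * shrink
    return float(out) if np.isscalar(gwas_z) or out.ndim == 0 else out


def lbf_sign_change_z2(prior_variance_w: float) -> float:
    """z^2 at which the per-eSNP LBF changes sign."""
    w = prior_variance_w
    return (1.0 + w) / w * math.log1p(w)


def lbf_to_bayes_factor(lbf: float) -> float:
    """Odds of association versus the null implied by a log Bayes factor."""
    if not math.isfinite(lbf):
        raise ValidationError("non-finite LBF")
    return math.exp(lbf)


def bonferroni(p: float, n_tests: int) -> float:
    """Bonferroni-corrected p-value, min(1, p * n_tests)."""
    if n_tests < 1:
        raise ParameterError("n_tests must be >= 1")
    return min(1.0, p * n_tests)


def find_esnps(
    eqtl: Sequence[EqtlAssociation],
    gene_id: str,
    esnp_p_threshold: float,
) -> list[tuple[str, float]]:
    """eSNPs of a gene: (snp_id, eQTL z) with eQTL p below the threshold.

    Sorted by ascending p-value, ties broken lexicographically by snp_id.
    A gene absent from the table yields an empty list.
    """
    if not (0.0 < esnp_p_threshold < 1.0):
        raise ParameterError("esnp_p_threshold must be in (0, 1)")
    hits = [
        rec for rec in eqtl
        if rec.gene_id == gene_id and rec.p_value < esnp_p_threshold
    ]
    hits.sort(key=lambda r: (r.p_value, r.snp_id))
    return [(r.snp_id, r.z_score) for r in hits]


def gene_lbf(
    esnps: Sequence[tuple[str, float]],
    gwas: Mapping[str, float],
    prior_variance_w: float,
    gene_id: str = "",
) -> GeneLbfResult:
    """Sum per-eSNP LBFs into a gene score.

    ``esnps`` are (snp_id, eqtl_z) pairs; ``gwas`` maps snp_id -> GWAS z.
    eSNPs with no GWAS record are dropped with a warning before summation.
    """
    if not esnps:
        raise ValidationError(f"gene {gene_id or '<unnamed>'} not testable: no eSNPs")
    kept_ids: list[str] = []
    lbfs: list[float] = []
    for snp_id, _eqtl_z in esnps:
        if snp_id not in gwas:
            logger.warning(
                "gene %s: eSNP %s has no GWAS record; dropped", gene_id, snp_id
            )
            continue
        kept_ids.append(snp_id)
        lbfs.append(esnp_lbf(gwas[snp_id], prior_variance_w))
    if not kept_ids:
        raise ValidationError(
            f"gene {gene_id or '<unnamed>'} not testable: no eSNP has a GWAS record"
        )
    total = float(sum(lbfs))
    top = kept_ids[int(np.argmax(lbfs))]
    return GeneLbfResult(
        gene_id=gene_id,
        esnp_ids=kept_ids,
        esnp_lbfs=[float(v) for v in lbfs],
        total_lbf=total,
        top_esnp=top,
    )


def null_total_lbfs(
    n_esnps: int,
    prior_variance_w: float,
    n_null_draws: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Total LBFs of ``n_null_draws`` null genes with ``n_esnps`` eSNPs each."""
    z = rng.standard_normal((n_null_draws, n_esnps))
    return np.sum(esnp_lbf(z, prior_variance_w), axis=1)


def lbf_empirical_p(
    observed_total_lbf: float,
    n_esnps: int,
    prior_variance_w: float,
    n_null_draws: int,
    seed,
    null_totals: np.ndarray | None = None,
) -> float:
    """Monte-Carlo p-value of a gene's total LBF against matched null genes.

    Uses the add-one convention (1 + #{null >= observed}) / (1 + n), so the
    smallest attainable p is 1 / (n + 1).  ``null_totals`` may be supplied to
    reuse a null sample across genes with the same eSNP count.
    """
    if n_esnps < 1:
        raise ParameterError("n_esnps must be >= 1")
    if n_null_draws < 100:
        raise ParameterError("n_null_draws must be >= 100")
    if null_totals is None:
        rng = np.random.default_rng(seed)
        null_totals = null_total_lbfs(n_esnps, prior_variance_w, n_null_draws, rng)
    k = int(np.count_nonzero(null_totals >= observed_total_lbf))
    return (1 + k) / (1 + len(null_totals))


def lbf_scan(
    gwas: Sequence[SnpAssociation],
    eqtl: Sequence[EqtlAssociation],
    config: PipelineConfig,
    seed: int | None = None,
) -> list[GeneLbfResult]:
    """Score every gene in the eQTL table and attach empirical/corrected p.

    Null draws are shared across genes with the same eSNP count; the child
    seed for each count derives deterministically from the scan seed, so the
    result is independent of gene order.  Bonferroni correction multiplies by
    the number of genes actually tested.
    """
    seed = config.rng_seed if seed is None else seed
    gwas_z = {r.snp_id: r.z_score for r in gwas}

    by_gene: dict[str, list[EqtlAssociation]] = {}
    for rec in eqtl:
        by_gene.setdefault(rec.gene_id, []).append(rec)

    results: list[GeneLbfResult] = []
    for gene_id in sorted(by_gene):
        esnps = find_esnps(by_gene[gene_id], gene_id, config.esnp_p_threshold)
        esnps = [(s, z) for s, z in esnps if s in gwas_z]
        if not esnps:
            logger.info("gene %s has no scoreable eSNP; skipped", gene_id)
            continue
        results.append(
            gene_lbf(esnps, gwas_z, config.lbf_prior_variance_w, gene_id=gene_id)
        )

    null_cache: dict[int, np.ndarray] = {}
    for res in results:
        k = len(res.esnp_ids)
        if k not in null_cache:
            rng = np.random.default_rng(np.random.SeedSequence([seed, k]))
            null_cache[k] = null_total_lbfs(
                k, config.lbf_prior_variance_w, config.n_null_draws_lbf, rng
            )
        res.empirical_p = lbf_empirical_p(
            res.total_lbf, k, config.lbf_prior_variance_w,
            config.n_null_draws_lbf, seed=None, null_totals=null_cache[k],
        )
    n_tested = len(results)
    for res in results:
        res.corrected_p = bonferroni(res.empirical_p, n_tested)
    results.sort(key=lambda r: (-r.total_lbf, r.gene_id))
    return results
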