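"""Summary-data Mendelian randomization with a single top cis-eQTL instrument.

Per gene, the most significant cis eQTL below the instrument threshold
serves as the instrument, and

    T_SMR = (z_gwas^2 * z_eqtl^2) / (z_gwas^2 + z_eqtl^2)

is referred to a 1-df chi-square upper tail.  T_SMR never exceeds either
squared z, is symmetric in its arguments and invariant to sign flips, and
approaches z_gwas^2 as the instrument strengthens.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping, Sequence

from scipy import stats as _stats

from .config import PipelineConfig
from .errors import ParameterError, ValidationError
from .lbf import bonferroni
from .types import EqtlAssociation, SmrResult, SnpAssociation

logger = logging.getLogger(__name__)


def select_instrument(
    eqtl: Sequence[EqtlAssociation],
    gene_id: str,
    instrument_p_threshold: float,
) -> tuple[str, float] | None:
    """Top cis instrument for a gene: smallest-p cis record below the threshold.

    Ties break lexicographically by snp_id.  Returns None when the gene has
    no qualifying cis eQTL (trans records never instrument).
    """
    if not (0.0 < instrument_p_threshold < 1.0):
        raise ParameterError("instrument_p_threshold must be in (0, 1)")
    hits = [
        r for r in eqtl
        if r.gene_id == gene_id and r.cis_trans == "cis"
        and r.p_value < instrument_p_threshold
    ]
    if not hits:
        return None
    best = min(hits, key=lambda r: (r.p_value, r.snp_id))
    return best.snp_id, best.z_score


def smr_stat(z_gwas: float, z_eqtl: float) -> float:
    """The single-instrument mediation statistic T_SMR (1-df chi-square)."""
    if z_eqtl == 0:
        raise ValidationError("z_eqtl = 0: instrument invalid")
    if not (math.isfinite(z_gwas) and math.isfinite(z_eqtl)):
        raise ValidationError("non-finite z-score")
    g2, e2 = z_gwas * z_gwas, z_eqtl * z_eqtl
    return g2 * e2 / (g2 + e2)


def smr_p(t_smr: float) -> float:
    """Upper-tail 1-df chi-square probability of T_SMR."""
    return float(_stats.chi2.sf(t_smr, df=1))


def smr_scan(
    gwas: Sequence[SnpAssociation],
    eqtl: Sequence[EqtlAssociation],
    config: PipelineConfig,
) -> list[SmrResult]:
    """Run SMR for every gene with a qualifying cis instrument.

    Genes without an instrument, or whose instrument has no GWAS record, are
    skipped with a log message.  Bonferroni correction is over the genes
    actually tested.
    """
    gwas_z: Mapping[str, float] = {r.snp_id: r.z_score for r in gwas}
    by_gene: dict[str, list[EqtlAssociation]] = {}
    for rec in eqtl:
        by_gene.setdefault(rec.gene_id, []).append(rec)

    results: list[SmrResult] = []
    for gene_id in sorted(by_gene):
        inst = select_instrument(
            by_gene[gene_id], gene_id, config.smr_instrument_p_threshold
        )
        if inst is None:
            logger.info("gene %s has no SMR instrument; skipped", gene_id)
            continue
        snp_id, z_eqtl = inst
        if snp_id not in gwas_z:
            logger.warning(
                "gene %s: instrument %s has no GWAS record; skipped",
                gene_id, snp_id,
            )
            continue
        t = smr_stat(gwas_z[snp_id], z_eqtl)
        results.append(
            SmrResult(
                gene_id=gene_id,
                instrument_snp=snp_id,
                z_gwas=float(gwas_z[snp_id]),
                z_eqtl=float(z_eqtl),
                t_smr=t,
                p_smr=smr_p(t),
            )
        )
    n_tested = len(results)
    for res in results:
        res.corrected_p = bonferroni(res.p_smr, n_tested)
    results.sort(key=lambda r: (r.p_smr, r.gene_id))
    return results
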