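"""Convergent-functional-genomics scoring: nine evidence channels, one point each.

Channels 1-6 derive from in-pipeline results — Bayesian eQTL-GWAS discovery,
PPI connectivity, co-expression connectivity, case-control differential
expression, discovery replication in an independent eQTL panel, and SMR.
Channels 7-9 (brain structure, cognition, functional assays) come from
external resources and are supplied as per-gene booleans; genes without a
supplied value default to False.

Per-channel award rules (documented defaults, configurable via alpha):
  - sherlock_discovery / sherlock_replication / smr: Bonferroni-corrected
    p < alpha;
  - ppi / coexpression: the set-level permutation test is significant
    (p < alpha) AND the gene itself contributes at least one cross edge
    (in >= 1 significant cluster for co-expression);
  - differential_expression: raw p < alpha in >= 1 region, with a consistent
    direction across all regions significant for that gene.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

from .types import (
    CFG_CHANNELS,
    CfgEvidence,
    DeResult,
    GeneLbfResult,
    PermutationTestResult,
    SmrResult,
)

logger = logging.getLogger(__name__)


def build_evidence(
    lbf_results: Sequence[GeneLbfResult],
    smr_results: Sequence[SmrResult] = (),
    ppi: tuple[PermutationTestResult, Mapping[str, int]] | None = None,
    coexpression: Mapping[
        str, tuple[PermutationTestResult, Mapping[str, int]]
    ] | None = None,
    de_results: Sequence[DeResult] = (),
    replication_lbf_results: Sequence[GeneLbfResult] = (),
    external_channels: Mapping[str, Mapping[str, bool]] | None = None,
    alpha: float = 0.05,
) -> list[CfgEvidence]:
    """Assemble the nine-channel evidence vector for every scored gene.

    ``ppi`` pairs the set-level permutation result with per-candidate-gene
    cross-edge counts; ``coexpression`` maps cluster name to such a pair.
    """
    genes = [r.gene_id for r in lbf_results]
    gene_set = set(genes)

    disc = {r.gene_id: r.corrected_p for r in lbf_results}
    repl = {r.gene_id: r.corrected_p for r in replication_lbf_results}
    smr_p = {r.gene_id: r.corrected_p for r in smr_results}

    ppi_genes: set[str] = set()
    if ppi is not None:
        test, edges = ppi
        if test.p_value < alpha or test.below_resolution:
            ppi_genes = {g for g, k in edges.items() if k >= 1}

    coexpr_genes: set[str] = set()
    if coexpression:
        for cluster, (test, edges) in coexpression.items():
            if test.p_value < alpha or test.below_resolution:
                coexpr_genes |= {g for g, k in edges.items() if k >= 1}

    de_sig: dict[str, set[str]] = {}
    for r in de_results:
        if r.p_two_sided < alpha:
            de_sig.setdefault(r.gene_id, set()).add(r.direction)
    de_genes = {g for g, dirs in de_sig.items() if len(dirs) == 1}

    ext = external_channels or {}
    unknown = set(ext) - gene_set
    if unknown:
        logger.warning(
            "external channels for %d gene(s) not in the scored set; ignored: %s",
            len(unknown), sorted(unknown)[:5],
        )

    out: list[CfgEvidence] = []
    for g in genes:
        g_ext = ext.get(g, {})
        channels = {
            "sherlock_discovery": disc.get(g) is not None and disc[g] < alpha,
            "ppi": g in ppi_genes,
            "coexpression": g in coexpr_genes,
            "differential_expression": g in de_genes,
            "sherlock_replication": repl.get(g) is not None and repl[g] < alpha,
            "smr": smr_p.get(g) is not None and smr_p[g] < alpha,
            "brain_structure": bool(g_ext.get("brain_structure", False)),
            "cognition": bool(g_ext.get("cognition", False)),
            "functional_assay": bool(g_ext.get("functional_assay", False)),
        }
        assert tuple(channels) == CFG_CHANNELS
        out.append(CfgEvidence(gene_id=g, channels=channels))
    return out


def rank_genes(
    evidence: Sequence[CfgEvidence],
    total_lbf: Mapping[str, float] | None = None,
) -> list[tuple[int, CfgEvidence, float]]:
    """Rank genes by descending CFG score; ties by descending total LBF,
    then gene id.  Returns (rank, evidence, total_lbf) triples, rank 1-based.
    """
    if not evidence:
        raise ValueError("rank_genes needs at least one gene")
    lbf = total_lbf or {}
    ordered = sorted(
        evidence,
        key=lambda e: (-e.score, -lbf.get(e.gene_id, float("-inf")), e.gene_id),
    )
    return [
        (i + 1, e, float(lbf.get(e.gene_id, float("nan"))))
        for i, e in enumerate(ordered)
    ]
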