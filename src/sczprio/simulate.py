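"""Synthetic GWAS/eQTL/expression/network fixtures with planted ground truth.

The generators emulate the statistical structure the downstream analyses
assume — a mostly-null GWAS with a handful of genes whose eSNPs carry
disease signal, an expression panel with developmental decay, a latent-factor
co-expression block and case/control shifts, and an Erdos-Renyi interaction
background with planted cross-set enrichment — so every stage is testable
without external downloads.  Every generator is a pure function of its
parameters and seed.
"""

from __future__ import annotations

from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ParameterError
from .types import (
    EqtlAssociation,
    ExpressionMatrix,
    SnpAssociation,
    SyntheticTruth,
    p_from_z,
)

#: Four-cluster grouping of brain regions used by the co-expression stage.
DEFAULT_CLUSTER_MAP: dict[str, str] = {
    "V1C": "V1C-STC", "STC": "V1C-STC",
    "DFC": "PFC-MSC", "MFC": "PFC-MSC",
    "HIP": "STR-AMY", "STR": "STR-AMY",
    "MD": "MD-CBC", "CBC": "MD-CBC",
}

#: Regions carrying case/control samples in the differential-expression stage.
DE_REGIONS: tuple[str, ...] = ("HIP", "DFC", "STR")


def default_donors() -> list[tuple[str, float, str]]:
    """A developmental donor panel: (donor id, post-conception days, stage).

    Seven donors fall in the embryonic/fetal-to-infancy window (<= ~4 months
    after birth) and four in the childhood/adult window (>= 8 years), so both
    windows of the early-vs-late comparison are populated.
    """
    ages = [
        (56.0, "8pcw"), (77.0, "11pcw"), (112.0, "16pcw"), (147.0, "21pcw"),
        (196.0, "28pcw"), (266.0, "birth"), (386.0, "4mo"),
        (996.0, "2yr"), (3186.0, "8yr"), (5026.0, "13yr"),
        (7946.0, "21yr"), (14866.0, "40yr"),
    ]
    return [(f"D{i + 1:02d}", a, s) for i, (a, s) in enumerate(ages)]


def _gene_ids(n: int) -> list[str]:
    return [f"G{i + 1:04d}" for i in range(n)]


def gen_gwas_eqtl(
    n_snps: int,
    n_genes: int,
    n_risk_genes: int,
    esnps_per_gene: int,
    gwas_effect_mu: float,
    eqtl_effect_mu: float,
    seed: int,
    cis_fraction: float = 1.0,
    gene_ids: Sequence[str] | None = None,
    risk_genes: Sequence[str] | None = None,
    snp_prefix: str = "rs",
) -> tuple[list[SnpAssociation], list[EqtlAssociation], SyntheticTruth]:
    """Simulate paired GWAS and eQTL summary statistics with planted risk genes.

    Every gene receives ``esnps_per_gene`` distinct eSNPs whose eQTL z-scores
    draw from Normal(eqtl_effect_mu, 1).  GWAS z-scores are standard normal
    for all SNPs except the eSNPs of the ``n_risk_genes`` planted risk genes,
    which draw Normal(gwas_effect_mu, 1).  With ``gwas_effect_mu = 0`` risk
    and null genes are statistically indistinguishable in the GWAS.
    """
    if esnps_per_gene < 1:
        raise ParameterError("esnps_per_gene must be >= 1")
    if n_risk_genes > n_genes:
        raise ParameterError("n_risk_genes cannot exceed n_genes")
    if esnps_per_gene * n_genes > n_snps:
        raise ParameterError(
            f"infeasible: {n_genes} genes x {esnps_per_gene} eSNPs "
            f"> {n_snps} SNPs"
        )
    if gwas_effect_mu < 0 or eqtl_effect_mu < 0:
        raise ParameterError("effect means must be non-negative")
    if not (0.0 <= cis_fraction <= 1.0):
        raise ParameterError("cis_fraction must be in [0, 1]")

    rng = np.random.default_rng(seed)
    snp_ids = [f"{snp_prefix}{i + 1:06d}" for i in range(n_snps)]
    genes = list(gene_ids) if gene_ids is not None else _gene_ids(n_genes)
    if len(genes) != n_genes:
        raise ParameterError("gene_ids length must equal n_genes")

    if risk_genes is not None:
        if len(risk_genes) != n_risk_genes:
            raise ParameterError("risk_genes length must equal n_risk_genes")
        risk = _pick(rng, genes, risk_genes, "risk_genes")
    else:
        risk = sorted(rng.choice(genes, size=n_risk_genes, replace=False).tolist())
    risk_set = set(risk)

    # assign each gene a disjoint block of eSNPs from a shuffled SNP pool
    perm = rng.permutation(n_snps)
    gwas_z = rng.standard_normal(n_snps)

    eqtl: list[EqtlAssociation] = []
    for gi, gene in enumerate(genes):
        idx = perm[gi * esnps_per_gene:(gi + 1) * esnps_per_gene]
        ez = rng.normal(eqtl_effect_mu, 1.0, size=esnps_per_gene)
        if gene in risk_set:
            gwas_z[idx] = rng.normal(gwas_effect_mu, 1.0, size=esnps_per_gene)
        for j, si in enumerate(idx):
            flag = "cis" if rng.random() < cis_fraction else "trans"
            eqtl.append(
                EqtlAssociation(
                    snp_id=snp_ids[si],
                    gene_id=gene,
                    z_score=float(ez[j]),
                    p_value=float(p_from_z(ez[j])),
                    cis_trans=flag,
                )
            )

    gwas = [
        SnpAssociation(snp_id=snp_ids[i], z_score=float(gwas_z[i]),
                       p_value=float(p_from_z(gwas_z[i])))
        for i in range(n_snps)
    ]
    truth = SyntheticTruth(risk_genes=risk, seeds={"gwas_eqtl": int(seed)})
    return gwas, eqtl, truth


def _pick(rng: np.random.Generator, genes: Sequence[str],
          spec: int | Sequence[str], what: str) -> list[str]:
    if isinstance(spec, (int, np.integer)):
        if spec > len(genes):
            raise ParameterError(f"{what}: cannot pick {spec} of {len(genes)} genes")
        return sorted(rng.choice(genes, size=int(spec), replace=False).tolist())
    missing = set(spec) - set(genes)
    if missing:
        raise ParameterError(f"{what}: genes not in universe: {sorted(missing)[:5]}")
    return sorted(spec)


def gen_expression_panel(
    n_genes: int,
    donors: Sequence[tuple[str, float, str]] | None = None,
    regions_per_cluster: dict[str, Sequence[str]] | None = None,
    early_high_genes: int | Sequence[str] = 0,
    decay: float = 0.0,
    coexpr_block: tuple[int | Sequence[str], float] | None = None,
    de_genes: int | Sequence[str] = 0,
    de_shift: float = 0.0,
    n_cases: int = 0,
    n_controls: int = 0,
    noise_sd: float = 1.0,
    seed: int = 0,
    baseline: float = 10.0,
    early_stage_max: float = 386.0,
    late_stage_min: float = 3186.0,
    gene_ids: Sequence[str] | None = None,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Simulate a genes x samples brain expression panel.

    Developmental donors contribute one sample per region (diagnosis NA).
    Early-high genes decline linearly in age between the early and late
    windows so their late-window mean is ``baseline * (1 - decay)``.
    Co-expression block genes share a per-sample latent factor with the given
    loading, yielding pairwise |r| near loading^2 / (loading^2 + noise_sd^2).
    Case/control donors are adults sampled in the DE regions; planted DE
    genes are shifted by ``de_shift`` in cases (random sign per gene).
    """
    if not (0.0 <= decay < 1.0):
        raise ParameterError("decay must be in [0, 1)")
    if noise_sd <= 0:
        raise ParameterError("noise_sd must be positive")
    donors = list(donors) if donors is not None else default_donors()
    n_early = sum(1 for _, a, _ in donors if a <= early_stage_max)
    n_late = sum(1 for _, a, _ in donors if a >= late_stage_min)
    if n_early < 2 or n_late < 2:
        raise ParameterError(
            f"need >= 2 donors in each developmental window "
            f"(got {n_early} early, {n_late} late)"
        )
    if regions_per_cluster is None:
        regions_per_cluster = {}
        for region, cluster in DEFAULT_CLUSTER_MAP.items():
            regions_per_cluster.setdefault(cluster, []).append(region)

    rng = np.random.default_rng(seed)
    genes = list(gene_ids) if gene_ids is not None else _gene_ids(n_genes)
    if len(genes) != n_genes:
        raise ParameterError("gene_ids length must equal n_genes")

    early = _pick(rng, genes, early_high_genes, "early_high_genes")
    de = _pick(rng, genes, de_genes, "de_genes")
    de_dirs = {g: float(rng.choice([-1.0, 1.0])) for g in de}
    block: list[str] = []
    loading = 0.0
    if coexpr_block is not None:
        block_spec, loading = coexpr_block
        block = _pick(rng, genes, block_spec, "coexpr_block")

    regions = sorted(r for rs in regions_per_cluster.values() for r in rs)

    sample_ids: list[str] = []
    meta_rows: list[dict] = []
    for donor, age, stage in donors:
        for region in regions:
            sid = f"{donor}_{region}"
            sample_ids.append(sid)
            meta_rows.append(
                {"sample_id": sid, "donor": donor, "region": region,
                 "age_days": float(age), "stage": stage, "diagnosis": "NA"}
            )
    adult_age, adult_stage = 12000.0, "adult"
    de_regions = [r for r in DE_REGIONS if r in regions] or regions[:1]
    for kind, prefix, count in (("case", "SZ", n_cases), ("control", "CT", n_controls)):
        for i in range(count):
            donor = f"{prefix}{i + 1:03d}"
            for region in de_regions:
                sid = f"{donor}_{region}"
                sample_ids.append(sid)
                meta_rows.append(
                    {"sample_id": sid, "donor": donor, "region": region,
                     "age_days": adult_age, "stage": adult_stage,
                     "diagnosis": kind}
                )
    meta = pd.DataFrame(meta_rows).set_index("sample_id")

    n_samples = len(sample_ids)
    ages = meta["age_days"].to_numpy()
    # age ramp: 0 in the early window, 1 in the late window, linear between
    ramp = np.clip(
        (ages - early_stage_max) / (late_stage_min - early_stage_max), 0.0, 1.0
    )
    latent = rng.standard_normal(n_samples)

    values = np.full((n_genes, n_samples), baseline, dtype=float)
    gene_index = {g: i for i, g in enumerate(genes)}
    for g in early:
        values[gene_index[g]] -= baseline * decay * ramp
    for g in block:
        values[gene_index[g]] += loading * latent
    is_case = (meta["diagnosis"] == "case").to_numpy()
    for g in de:
        values[gene_index[g], is_case] += de_dirs[g] * de_shift
    values += noise_sd * rng.standard_normal((n_genes, n_samples))

    expr = ExpressionMatrix(
        values=pd.DataFrame(values, index=pd.Index(genes, name="gene_id"),
                            columns=sample_ids),
        meta=meta,
    )
    truth = SyntheticTruth(
        de_genes={g: de_dirs[g] * de_shift for g in de},
        early_high_genes=early,
        coexpr_block_genes=block,
        seeds={"expression": int(seed)},
    )
    return expr, truth


def gen_network(
    genes: Sequence[str],
    background_edge_prob: float,
    set_a: Sequence[str],
    set_b: Sequence[str],
    cross_edge_prob: float,
    seed: int,
) -> tuple[nx.Graph, SyntheticTruth]:
    """Simple undirected random graph with planted cross-set enrichment.

    Pairs with one endpoint in set_a and the other in set_b are drawn at
    ``cross_edge_prob``; all other pairs at ``background_edge_prob``.  A pair
    whose endpoints both lie in the A/B overlap is assigned the cross
    probability once (no double draw).
    """
    for name, p in (("background_edge_prob", background_edge_prob),
                    ("cross_edge_prob", cross_edge_prob)):
        if not (0.0 <= p <= 1.0):
            raise ParameterError(f"{name} must be in [0, 1], got {p!r}")
    genes = list(genes)
    if len(set(genes)) != len(genes):
        raise ParameterError("gene universe contains duplicates")
    missing = (set(set_a) | set(set_b)) - set(genes)
    if missing:
        raise ParameterError(f"set members outside universe: {sorted(missing)[:5]}")

    rng = np.random.default_rng(seed)
    n = len(genes)
    in_a = np.array([g in set(set_a) for g in genes])
    in_b = np.array([g in set(set_b) for g in genes])
    iu, ju = np.triu_indices(n, k=1)
    cross = (in_a[iu] & in_b[ju]) | (in_b[iu] & in_a[ju])
    probs = np.where(cross, cross_edge_prob, background_edge_prob)
    draws = rng.random(len(iu)) < probs

    net = nx.Graph()
    net.add_nodes_from(genes)
    for i, j in zip(iu[draws], ju[draws]):
        net.add_edge(genes[i], genes[j])
    truth = SyntheticTruth(
        enriched_candidate_set=sorted(set_a),
        seeds={"network": int(seed)},
    )
    return net, truth


def simulate_bundle(
    outdir,
    seed: int,
    n_snps: int = 1000,
    n_genes: int = 100,
    n_risk_genes: int = 3,
    esnps_per_gene: int = 5,
    gwas_effect_mu: float = 5.0,
    eqtl_effect_mu: float = 7.0,
    n_reference: int = 50,
    background_edge_prob: float = 0.02,
    cross_edge_prob: float = 0.5,
    decay: float = 0.7,
    coexpr_loading: float = 6.0,
    coexpr_block_reference: int = 20,
    de_shift: float = 2.0,
    n_cases: int = 19,
    n_controls: int = 19,
    noise_sd: float = 1.0,
    with_replication: bool = True,
):
    """Write a complete, internally consistent input bundle for the pipeline.

    Planted structure: ``n_risk_genes`` genes carry GWAS signal at their
    eSNPs (discovery and, optionally, an independent replication eQTL panel
    with its own SNPs), are early-high in development, share a latent
    co-expression factor with ``coexpr_block_reference`` reference genes,
    are shifted in cases, and have excess PPI edges to the reference set.
    Null scenarios follow by setting the effect knobs to their no-signal
    values (gwas_effect_mu=0, cross_edge_prob=background_edge_prob, decay=0,
    de_shift=0, coexpr_loading=0).

    Returns (PipelineInputs, SyntheticTruth); the truth ledger is also
    written to ``truth.json`` in the bundle directory.
    """
    import json
    from pathlib import Path

    from . import io as _io
    from .pipeline import PipelineInputs

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    sub = [int(s.generate_state(1)[0] >> 1) for s in ss.spawn(5)]

    gwas, eqtl, truth = gen_gwas_eqtl(
        n_snps=n_snps, n_genes=n_genes, n_risk_genes=n_risk_genes,
        esnps_per_gene=esnps_per_gene, gwas_effect_mu=gwas_effect_mu,
        eqtl_effect_mu=eqtl_effect_mu, seed=sub[0],
    )
    risk = truth.risk_genes
    genes = _gene_ids(n_genes)
    reference = [f"R{i + 1:03d}" for i in range(n_reference)]

    if with_replication:
        gwas2, eqtl2, truth2 = gen_gwas_eqtl(
            n_snps=n_snps, n_genes=n_genes, n_risk_genes=n_risk_genes,
            esnps_per_gene=esnps_per_gene, gwas_effect_mu=gwas_effect_mu,
            eqtl_effect_mu=eqtl_effect_mu, seed=sub[1],
            risk_genes=risk, snp_prefix="rr",
        )
        gwas = gwas + gwas2
        truth = truth.merged(truth2)

    block = sorted(set(risk) | set(reference[:coexpr_block_reference]))
    expr, truth_e = gen_expression_panel(
        n_genes=n_genes + n_reference,
        gene_ids=genes + reference,
        early_high_genes=risk,
        decay=decay,
        coexpr_block=(block, coexpr_loading) if coexpr_loading > 0 else None,
        de_genes=risk,
        de_shift=de_shift,
        n_cases=n_cases,
        n_controls=n_controls,
        noise_sd=noise_sd,
        seed=sub[2],
    )
    truth = truth.merged(truth_e)

    net, truth_n = gen_network(
        genes + reference, background_edge_prob, risk, reference,
        cross_edge_prob, seed=sub[3],
    )
    truth = truth.merged(truth_n)
    truth.seeds["bundle"] = int(seed)

    paths = PipelineInputs(
        gwas=outdir / "gwas.tsv",
        eqtl=outdir / "eqtl.tsv",
        expression=outdir / "expression.tsv",
        expression_meta=outdir / "expression_meta.tsv",
        network=outdir / "network.tsv",
        reference_genes=outdir / "reference_genes.txt",
        cluster_map=outdir / "cluster_map.tsv",
        background_genes=outdir / "background_genes.txt",
        replication_eqtl=outdir / "replication_eqtl.tsv" if with_replication else None,
        truth=outdir / "truth.json",
    )
    _io.write_gwas_summary(gwas, paths.gwas)
    _io.write_eqtl_table(eqtl, paths.eqtl)
    if with_replication:
        _io.write_eqtl_table(eqtl2, paths.replication_eqtl)
    _io.write_expression(expr, paths.expression, paths.expression_meta)
    _io.write_network(net, paths.network)
    _io.write_gene_set(reference, paths.reference_genes)
    _io.write_gene_set(genes, paths.background_genes)
    _io.write_cluster_map(DEFAULT_CLUSTER_MAP, paths.cluster_map)
    with open(paths.truth, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths, truth
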