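"""End-to-end orchestration: read inputs, run every stage, write result tables.

Stage order: LBF scoring -> SMR -> PPI permutation -> co-expression
permutation -> developmental-pattern permutation -> case-control DE -> CFG
ranking.  Candidate genes for the set-level evidence stages are the genes
significant after Bonferroni correction in the LBF stage (falling back to
the top ten by LBF when nothing is significant, so null runs still exercise
every stage).  All stochastic stages derive their seeds deterministically
from the config seed, and result tables are written with full float
precision, so a rerun with the same seed and inputs is byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import io as _io
from .cfg import build_evidence, rank_genes
from .config import PipelineConfig
from .de import de_scan
from .devexpr import pattern_permutation_test
from .errors import PipelineStageError
from .lbf import lbf_scan
from .network import (
    coexpression_network,
    coexpression_permutation_test,
    per_gene_cross_edges,
    ppi_permutation_test,
)
from .smr import smr_scan

logger = logging.getLogger(__name__)

#: fixed per-stage offsets for deriving child seeds from the config seed
_STAGE_SEEDS = {"lbf": 1, "replication_lbf": 2, "ppi": 3, "coexpr": 4, "pattern": 5}


@dataclass
class PipelineInputs:
    gwas: Path
    eqtl: Path
    expression: Path
    expression_meta: Path
    network: Path
    reference_genes: Path
    cluster_map: Path
    background_genes: Path | None = None
    replication_eqtl: Path | None = None
    external_channels: Path | None = None
    truth: Path | None = None

    def as_dict(self) -> dict[str, Path]:
        d = {
            "gwas": self.gwas,
            "eqtl": self.eqtl,
            "expression": self.expression,
            "expression_meta": self.expression_meta,
            "network": self.network,
            "reference_genes": self.reference_genes,
            "cluster_map": self.cluster_map,
        }
        for name in ("background_genes", "replication_eqtl",
                     "external_channels", "truth"):
            p = getattr(self, name)
            if p is not None:
                d[name] = p
        return d


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:
                raise PipelineStageError(name, exc) from exc
        return wrapped
    return deco


def _child_seed(base: int, stage: str) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(base), _STAGE_SEEDS[stage]])


def run_pipeline(
    config: PipelineConfig,
    inputs: PipelineInputs,
    outdir: str | Path,
) -> dict[str, Path]:
    """Run every stage on the given input files and write the results bundle.

    Writes seven stage tables (lbf, smr, ppi_perm, coexpr_perm, pattern_perm,
    de, cfg_ranking) plus a manifest recording config, seed, and input
    checksums.  Any stage failure aborts with the stage name and cause.
    Returns a mapping from stage name to the written path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.rng_seed

    # ---- load inputs
    try:
        gwas = _io.read_gwas_summary(inputs.gwas)
        eqtl = _io.read_eqtl_table(inputs.eqtl)
        expr = _io.read_expression(inputs.expression, inputs.expression_meta)
        net = _io.read_network(inputs.network)
        reference = _io.read_gene_set(inputs.reference_genes)
        cluster_map = _io.read_cluster_map(inputs.cluster_map)
        eqtl_genes = sorted({r.gene_id for r in eqtl})
        background = (
            _io.read_gene_set(inputs.background_genes)
            if inputs.background_genes is not None else eqtl_genes
        )
        replication_eqtl = (
            _io.read_eqtl_table(inputs.replication_eqtl)
            if inputs.replication_eqtl is not None else None
        )
        truth = None
        if inputs.truth is not None:
            import json
            with open(inputs.truth) as fh:
                truth = json.load(fh)
    except Exception as exc:
        raise PipelineStageError("load_inputs", exc) from exc

    paths: dict[str, Path] = {}

    # ---- stage 1: LBF scoring
    @_stage("lbf")
    def run_lbf():
        results = lbf_scan(
            gwas, eqtl, config,
            seed=int(_child_seed(seed, "lbf").generate_state(1)[0] >> 1),
        )
        df = _io.lbf_results_frame(results)
        p = outdir / "lbf.tsv"
        _io.write_result_table(df, p)
        return results, p

    lbf_results, paths["lbf"] = run_lbf()
    total_lbf = {r.gene_id: r.total_lbf for r in lbf_results}
    significant = [
        r.gene_id for r in lbf_results
        if r.corrected_p is not None and r.corrected_p < config.alpha
    ]
    if significant:
        candidates = significant
    else:
        candidates = [r.gene_id for r in lbf_results[:10]]
        logger.warning(
            "no gene passed Bonferroni-corrected p < %g; carrying the top %d "
            "genes by LBF forward as candidates", config.alpha, len(candidates),
        )
    logger.info("candidate set for evidence stages: %s", candidates)

    # ---- stage 2: SMR
    @_stage("smr")
    def run_smr():
        results = smr_scan(gwas, eqtl, config)
        p = outdir / "smr.tsv"
        _io.write_result_table(_io.smr_results_frame(results), p)
        return results, p

    smr_results, paths["smr"] = run_smr()

    # ---- stage 3: PPI permutation
    @_stage("ppi_perm")
    def run_ppi():
        test = ppi_permutation_test(
            candidates, reference, net, background,
            config.n_permutations, _child_seed(seed, "ppi"),
        )
        edges = per_gene_cross_edges(candidates, reference, net)
        p = outdir / "ppi_perm.tsv"
        _io.write_result_table(
            _io.permutation_results_frame({"ppi": test}), p
        )
        return (test, edges), p

    ppi_pair, paths["ppi_perm"] = run_ppi()

    # ---- stage 4: co-expression permutation, per region cluster
    @_stage("coexpr_perm")
    def run_coexpr():
        tests = coexpression_permutation_test(
            expr, cluster_map, candidates, reference, background,
            config.coexpr_r_threshold, config.n_permutations,
            _child_seed(seed, "coexpr"),
        )
        pairs = {}
        for cluster, test in tests.items():
            g = coexpression_network(
                expr, cluster, cluster_map, candidates, reference,
                config.coexpr_r_threshold,
            )
            ref_set = set(reference)
            degs = {
                c: sum(1 for nb in g.adj[c] if nb in ref_set) if c in g else 0
                for c in candidates
            }
            pairs[cluster] = (test, degs)
        p = outdir / "coexpr_perm.tsv"
        _io.write_result_table(
            _io.permutation_results_frame(
                {cl: t for cl, (t, _) in sorted(pairs.items())}
            ),
            p,
        )
        return pairs, p

    coexpr_pairs, paths["coexpr_perm"] = run_coexpr()

    # ---- stage 5: developmental-pattern permutation
    @_stage("pattern_perm")
    def run_pattern():
        test = pattern_permutation_test(
            expr, candidates, background, config.n_permutations,
            _child_seed(seed, "pattern"),
            config.early_stage_max, config.late_stage_min,
        )
        p = outdir / "pattern_perm.tsv"
        _io.write_result_table(
            _io.permutation_results_frame({"early_vs_late": test}), p
        )
        return test, p

    _pattern_test, paths["pattern_perm"] = run_pattern()

    # ---- stage 6: case-control differential expression
    @_stage("de")
    def run_de():
        results = de_scan(expr, candidates, equal_var=config.de_equal_var)
        p = outdir / "de.tsv"
        _io.write_result_table(_io.de_results_frame(results), p)
        return results, p

    de_results, paths["de"] = run_de()

    # ---- optional replication LBF (channel 5)
    replication_results = []
    if replication_eqtl is not None:
        @_stage("replication_lbf")
        def run_repl():
            return lbf_scan(
                gwas, replication_eqtl, config,
                seed=int(
                    _child_seed(seed, "replication_lbf").generate_state(1)[0] >> 1
                ),
            )
        replication_results = run_repl()

    # ---- stage 7: CFG ranking
    @_stage("cfg")
    def run_cfg():
        external = (
            _io.read_external_channels(
                inputs.external_channels,
                known_genes=[r.gene_id for r in lbf_results],
            )
            if inputs.external_channels is not None else None
        )
        evidence = build_evidence(
            lbf_results,
            smr_results=smr_results,
            ppi=ppi_pair,
            coexpression=coexpr_pairs,
            de_results=de_results,
            replication_lbf_results=replication_results,
            external_channels=external,
            alpha=config.alpha,
        )
        ranking = rank_genes(evidence, total_lbf)
        p = outdir / "cfg_ranking.tsv"
        _io.write_result_table(_io.cfg_ranking_frame(ranking), p)
        return ranking, p

    _ranking, paths["cfg"] = run_cfg()

    manifest_path = outdir / "manifest.json"
    _io.write_manifest(
        manifest_path, config, seed,
        inputs={k: str(v) for k, v in inputs.as_dict().items()},
        outputs=[p.name for p in paths.values()],
        truth=truth,
    )
    paths["manifest"] = manifest_path
    return paths
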