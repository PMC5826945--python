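"""Permutation tests of cross-set connectivity in PPI and co-expression graphs.

The question each test asks: is a candidate gene set more connected to a
reference (GWAS-significant) gene set than size-matched random gene sets
drawn from a background universe?  The statistic is the number of network
edges with one endpoint in the candidate set and the other in the reference
set; edges internal to either set are excluded, and a gene belonging to both
sets is counted on the reference side.  The permutation p-value is the plain
exceedance fraction k/n, reported as "< 1/n" when no permutation reaches the
observed value.

Random draws come from the background with the reference genes removed, so
a permuted set can never inflate its connectivity by containing reference
genes; the effective draw size matches the number of measurable candidate
genes (candidates present in the graph / expression panel), mirroring how
candidates missing from a resource drop out of the observed statistic.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ParameterError, ValidationError
from .types import ExpressionMatrix, PermutationTestResult

logger = logging.getLogger(__name__)


def cross_connectivity(
    candidates: Iterable[str], reference: Iterable[str], net: nx.Graph
) -> int:
    """Number of edges joining candidates \\ reference to the reference set.

    Genes absent from the network contribute no edges; the count is symmetric
    in the two sets.
    """
    ref = set(reference)
    cand = (set(candidates) - ref)
    count = 0
    for c in cand:
        if c not in net:
            continue
        count += sum(1 for nb in net.adj[c] if nb in ref)
    return count


def per_gene_cross_edges(
    candidates: Iterable[str], reference: Iterable[str], net: nx.Graph
) -> dict[str, int]:
    """Edges into the reference set, per candidate gene (reference members -> 0)."""
    ref = set(reference)
    out: dict[str, int] = {}
    for c in set(candidates):
        if c in ref or c not in net:
            out[c] = 0
        else:
            out[c] = sum(1 for nb in net.adj[c] if nb in ref)
    return out


def _permutation_pvalue(
    observed: float,
    gene_scores: Mapping[str, float],
    pool: Sequence[str],
    draw_size: int,
    n_permutations: int,
    seed,
) -> PermutationTestResult:
    """Generic matched-size redraw test for a sum-over-genes statistic."""
    if n_permutations < 1:
        raise ParameterError("n_permutations must be >= 1")
    if draw_size > len(pool):
        raise ParameterError(
            f"background too small: draw size {draw_size} > pool {len(pool)}"
        )
    pool_arr = np.array(sorted(pool))
    scores = np.array([gene_scores.get(g, 0) for g in pool_arr], dtype=float)
    rng = np.random.default_rng(seed)
    n_exceeding = 0
    if draw_size == 0:
        # nothing to draw: every permutation scores 0
        n_exceeding = n_permutations if 0 >= observed else 0
    else:
        for _ in range(n_permutations):
            idx = rng.choice(len(pool_arr), size=draw_size, replace=False)
            if scores[idx].sum() >= observed:
                n_exceeding += 1
    return PermutationTestResult(
        observed_statistic=float(observed),
        n_permutations=int(n_permutations),
        n_exceeding=int(n_exceeding),
        seed=int(seed) if isinstance(seed, (int, np.integer)) else None,
        draw_size=int(draw_size),
    )


def ppi_permutation_test(
    candidates: Sequence[str],
    reference: Sequence[str],
    net: nx.Graph,
    background: Sequence[str],
    n_permutations: int,
    seed,
) -> PermutationTestResult:
    """Cross-set PPI connectivity versus size-matched random gene sets.

    Permuted sets draw, without replacement, as many genes as the candidate
    set has measurable members (present in the graph, outside the reference)
    from background \\ reference.
    """
    cand_set = set(candidates)
    bg = set(background)
    if not cand_set <= bg:
        raise ParameterError("candidates must be a subset of the background")
    ref = set(reference)
    observed = cross_connectivity(cand_set, ref, net)
    measurable = [g for g in cand_set - ref if g in net]
    dropped = (cand_set - ref) - set(measurable)
    if dropped:
        logger.warning(
            "%d candidate gene(s) absent from network; draw size reduced to %d",
            len(dropped), len(measurable),
        )
    pool = sorted(bg - ref)
    deg = per_gene_cross_edges(pool, ref, net)
    return _permutation_pvalue(
        observed, deg, pool, len(measurable), n_permutations, seed
    )


def _cluster_values(
    expr: ExpressionMatrix, cluster_map: dict[str, str], cluster: str
) -> pd.DataFrame:
    samples = expr.cluster_samples(cluster_map, cluster)
    if len(samples) < 3:
        raise ValidationError(
            f"cluster {cluster!r} has {len(samples)} sample(s); need >= 3"
        )
    return expr.values[samples]


def _abs_corr_matrix(
    vals: pd.DataFrame, rows: list[str], cols: list[str]
) -> tuple[np.ndarray, list[str], list[str]]:
    """|Pearson r| between row genes and column genes over the given samples.

    Zero-variance genes are excluded (correlation undefined) with a log line.
    """
    keep_rows, keep_cols = [], []
    mat = vals.to_numpy(dtype=float)
    idx = {g: i for i, g in enumerate(vals.index)}
    sd = mat.std(axis=1)
    dropped = []
    for name, keep in ((rows, keep_rows), (cols, keep_cols)):
        for g in name:
            if g not in idx:
                continue
            if sd[idx[g]] == 0:
                dropped.append(g)
                continue
            keep.append(g)
    if dropped:
        logger.warning(
            "excluded %d zero-variance gene(s) from co-expression: %s",
            len(dropped), sorted(set(dropped))[:5],
        )
    if not keep_rows or not keep_cols:
        return np.zeros((len(keep_rows), len(keep_cols))), keep_rows, keep_cols
    centered = mat - mat.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered ** 2).sum(axis=1))
    ri = [idx[g] for g in keep_rows]
    ci = [idx[g] for g in keep_cols]
    r = centered[ri] @ centered[ci].T / np.outer(norms[ri], norms[ci])
    return np.abs(r), keep_rows, keep_cols


def coexpression_network(
    expr: ExpressionMatrix,
    cluster: str,
    cluster_map: dict[str, str],
    genes_a: Sequence[str],
    genes_b: Sequence[str],
    r_threshold: float,
) -> nx.Graph:
    """Cross-set co-expression graph for one region cluster.

    Nodes are the genes of either set present in the matrix; an edge joins
    g in genes_a to h in genes_b when |Pearson r| over the cluster's samples
    exceeds the threshold.
    """
    if not (0.0 < r_threshold < 1.0):
        raise ParameterError("r_threshold must be in (0, 1)")
    vals = _cluster_values(expr, cluster_map, cluster)
    absr, rows, cols = _abs_corr_matrix(vals, list(genes_a), list(genes_b))
    net = nx.Graph()
    net.add_nodes_from(g for g in set(genes_a) | set(genes_b) if g in expr.genes)
    for i, g in enumerate(rows):
        for j, h in enumerate(cols):
            if g != h and absr[i, j] > r_threshold:
                net.add_edge(g, h)
    return net


def coexpression_permutation_test(
    expr: ExpressionMatrix,
    cluster_map: dict[str, str],
    candidates: Sequence[str],
    reference: Sequence[str],
    background: Sequence[str],
    r_threshold: float,
    n_permutations: int,
    seed,
    clusters: Sequence[str] | None = None,
) -> dict[str, PermutationTestResult]:
    """Per-cluster permutation test of candidate-reference co-expression.

    For each cluster, the observed statistic is the number of candidate-
    reference gene pairs with |r| above the threshold; permuted sets redraw
    candidate-sized gene sets from background \\ reference.
    """
    cand_set = set(candidates)
    bg = set(background)
    if not cand_set <= bg:
        raise ParameterError("candidates must be a subset of the background")
    ref = set(reference)
    if clusters is None:
        clusters = sorted(set(cluster_map.values()))
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    seeds = ss.spawn(len(clusters))
    results: dict[str, PermutationTestResult] = {}
    for cluster, child in zip(clusters, seeds):
        vals = _cluster_values(expr, cluster_map, cluster)
        pool_all = sorted((bg | cand_set) - ref)
        absr, rows, cols = _abs_corr_matrix(vals, pool_all, sorted(ref))
        edges = absr > r_threshold
        row_counts = dict(zip(rows, edges.sum(axis=1).astype(int)))
        measurable = [g for g in cand_set - ref if g in row_counts]
        observed = sum(row_counts[g] for g in measurable)
        pool = sorted(set(rows) & (bg - ref))
        results[cluster] = _permutation_pvalue(
            observed, row_counts, pool, len(measurable), n_permutations, child
        )
    return results
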