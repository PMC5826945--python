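"""Readers and writers for the tabular formats the pipeline consumes and emits.

All tables are tab-separated with a header row; lines starting with '#' are
comments.  Floats in result tables are written with 17 significant digits so
a write-then-read round trip reproduces every value exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .types import (
    CFG_CHANNELS,
    CfgEvidence,
    DeResult,
    EqtlAssociation,
    ExpressionMatrix,
    GeneLbfResult,
    PermutationTestResult,
    SmrResult,
    SnpAssociation,
    p_from_z,
    z_from_p,
)

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.17g"


def _read_table(path: str | Path, what: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{what} file not found: {path}")
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str},
                         float_precision="round_trip")
    except pd.errors.EmptyDataError:
        return pd.DataFrame()
    return df


def _require_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{what}: missing required column '{col}'")


def _fill_z_p(df: pd.DataFrame, what: str) -> pd.DataFrame:
    """Reconcile z and p columns; recover |z| from p when z is absent."""
    has_p = "p" in df.columns
    has_z = "z" in df.columns
    if not (has_p or has_z):
        raise FormatError(f"{what}: need at least one of columns 'p', 'z'")
    out = df.copy()
    if has_p:
        p = pd.to_numeric(out["p"], errors="coerce")
        bad = p.isna() | (p <= 0) | (p > 1)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise ValidationError(
                f"{what}: p-value outside (0, 1] at data row {row}"
            )
        out["p"] = p
    if has_z:
        z = pd.to_numeric(out["z"], errors="coerce")
        if z.isna().any():
            row = int(np.flatnonzero(z.isna().to_numpy())[0]) + 1
            raise ValidationError(f"{what}: non-numeric z at data row {row}")
        out["z"] = z
    if has_z and not has_p:
        out["p"] = p_from_z(out["z"].to_numpy())
    if has_p and not has_z:
        out["z"] = z_from_p(out["p"].to_numpy())
        out["sign_known"] = False
    else:
        out["sign_known"] = True
    return out


def read_gwas_summary(path: str | Path) -> list[SnpAssociation]:
    """Read GWAS summary statistics: columns snp_id and p and/or z.

    When only p is given, |z| is recovered via the two-sided normal quantile
    and the record is flagged sign-unknown.  Duplicate snp_ids are rejected.
    """
    df = _read_table(path, "GWAS summary")
    if df.empty:
        logger.warning("GWAS summary file %s is empty", path)
        return []
    _require_columns(df, ["snp_id"], "GWAS summary")
    df = _fill_z_p(df, "GWAS summary")
    dup = df["snp_id"][df["snp_id"].duplicated()]
    if not dup.empty:
        raise FormatError(
            f"GWAS summary: duplicate snp_id(s): {sorted(set(dup))[:5]}"
        )
    return [
        SnpAssociation(
            snp_id=str(r.snp_id),
            z_score=float(r.z),
            p_value=float(r.p),
            sign_known=bool(r.sign_known),
        )
        for r in df.itertuples()
    ]


def read_eqtl_table(path: str | Path) -> list[EqtlAssociation]:
    """Read an eQTL table: columns snp_id, gene_id, p and/or z, cis_trans."""
    df = _read_table(path, "eQTL table")
    if df.empty:
        logger.warning("eQTL table %s is empty", path)
        return []
    _require_columns(df, ["snp_id", "gene_id", "cis_trans"], "eQTL table")
    df = _fill_z_p(df, "eQTL table")
    bad = ~df["cis_trans"].isin(["cis", "trans"])
    if bad.any():
        tok = df["cis_trans"][bad].iloc[0]
        raise ValidationError(f"eQTL table: unknown cis_trans token {tok!r}")
    pairs = df[["snp_id", "gene_id"]].apply(tuple, axis=1)
    dup = pairs[pairs.duplicated()]
    if not dup.empty:
        raise FormatError(
            f"eQTL table: duplicate (snp, gene) pair(s): {sorted(set(dup))[:5]}"
        )
    return [
        EqtlAssociation(
            snp_id=str(r.snp_id),
            gene_id=str(r.gene_id),
            z_score=float(r.z),
            p_value=float(r.p),
            cis_trans=str(r.cis_trans),
            sign_known=bool(r.sign_known),
        )
        for r in df.itertuples()
    ]


def write_gwas_summary(records: Sequence[SnpAssociation], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "snp_id": [r.snp_id for r in records],
            "z": [r.z_score for r in records],
            "p": [r.p_value for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_eqtl_table(records: Sequence[EqtlAssociation], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "snp_id": [r.snp_id for r in records],
            "gene_id": [r.gene_id for r in records],
            "z": [r.z_score for r in records],
            "p": [r.p_value for r in records],
            "cis_trans": [r.cis_trans for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_gene_set(path: str | Path) -> list[str]:
    """One gene id per line; '#' comments and blank lines ignored."""
    genes: list[str] = []
    seen = set()
    with open(path) as fh:
        for line in fh:
            g = line.split("#", 1)[0].strip()
            if not g:
                continue
            if g not in seen:
                genes.append(g)
                seen.add(g)
    return genes


def write_gene_set(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def read_network(path: str | Path) -> nx.Graph:
    """Two-column TSV edge list -> simple undirected graph.

    Self-loops are dropped with a warning; duplicate edges collapse.
    """
    df = _read_table(path, "network edge list")
    net = nx.Graph()
    if df.empty:
        logger.warning("network file %s is empty", path)
        return net
    if df.shape[1] < 2:
        raise FormatError("network edge list: need two columns")
    a, b = df.columns[:2]
    n_self = 0
    for u, v in zip(df[a].astype(str), df[b].astype(str)):
        if u == v:
            n_self += 1
            continue
        net.add_edge(u, v)
    if n_self:
        logger.warning("dropped %d self-loop edge(s) from %s", n_self, path)
    return net


def write_network(net: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\n")
        for u, v in sorted(tuple(sorted(e)) for e in net.edges()):
            fh.write(f"{u}\t{v}\n")


def read_expression(values_path: str | Path, meta_path: str | Path) -> ExpressionMatrix:
    vals = _read_table(values_path, "expression matrix")
    if vals.empty:
        raise FormatError(f"expression matrix {values_path} is empty")
    vals = vals.set_index(vals.columns[0])
    vals.index.name = "gene_id"
    vals = vals.apply(pd.to_numeric)
    meta = _read_table(meta_path, "sample metadata")
    if meta.empty:
        raise FormatError(f"sample metadata {meta_path} is empty")
    meta = meta.set_index(meta.columns[0])
    meta.index.name = "sample_id"
    meta.index = meta.index.astype(str)
    if "diagnosis" in meta.columns:
        # the literal token NA means "not a case/control sample"
        meta["diagnosis"] = meta["diagnosis"].fillna("NA").astype(str)
    vals.columns = vals.columns.astype(str)
    return ExpressionMatrix(values=vals, meta=meta)


def write_expression(expr: ExpressionMatrix, values_path: str | Path,
                     meta_path: str | Path) -> None:
    expr.values.to_csv(values_path, sep="\t", float_format=_FLOAT_FMT)
    expr.meta.to_csv(meta_path, sep="\t")


def read_cluster_map(path: str | Path) -> dict[str, str]:
    """TSV with columns region, cluster -> mapping region -> cluster name."""
    df = _read_table(path, "region-cluster map")
    _require_columns(df, ["region", "cluster"], "region-cluster map")
    dup = df["region"][df["region"].duplicated()]
    if not dup.empty:
        raise FormatError(
            f"region-cluster map: region(s) mapped twice: {sorted(set(dup))}"
        )
    return dict(zip(df["region"].astype(str), df["cluster"].astype(str)))


def write_cluster_map(cluster_map: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("region\tcluster\n")
        for region, cluster in sorted(cluster_map.items()):
            fh.write(f"{region}\t{cluster}\n")


def read_external_channels(path: str | Path,
                           known_genes: Iterable[str] | None = None
                           ) -> dict[str, dict[str, bool]]:
    """TSV with columns gene_id, channel, value (0/1).

    Channels must be among the three external CFG channels.  Rows for genes
    outside ``known_genes`` (when given) are ignored with a warning.
    """
    external = set(CFG_CHANNELS[6:])
    df = _read_table(path, "external channels")
    if df.empty:
        return {}
    _require_columns(df, ["gene_id", "channel", "value"], "external channels")
    bad = ~df["channel"].isin(external)
    if bad.any():
        raise ValidationError(
            f"external channels: unknown channel {df['channel'][bad].iloc[0]!r}; "
            f"allowed: {sorted(external)}"
        )
    known = set(known_genes) if known_genes is not None else None
    out: dict[str, dict[str, bool]] = {}
    skipped = []
    for r in df.itertuples():
        g = str(r.gene_id)
        if known is not None and g not in known:
            skipped.append(g)
            continue
        out.setdefault(g, {})[str(r.channel)] = bool(int(r.value))
    if skipped:
        logger.warning(
            "external channels: ignored %d row(s) for unknown gene(s) e.g. %s",
            len(skipped), skipped[:3],
        )
    return out


# ---------------------------------------------------------------- result tables

def lbf_results_frame(results: Sequence[GeneLbfResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in results],
            "total_lbf": [r.total_lbf for r in results],
            "empirical_p": [r.empirical_p for r in results],
            "corrected_p": [r.corrected_p for r in results],
            "n_esnps": [len(r.esnp_ids) for r in results],
            "top_esnp": [r.top_esnp for r in results],
            "esnp_ids": [",".join(r.esnp_ids) for r in results],
        }
    )


def smr_results_frame(results: Sequence[SmrResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in results],
            "instrument_snp": [r.instrument_snp for r in results],
            "z_gwas": [r.z_gwas for r in results],
            "z_eqtl": [r.z_eqtl for r in results],
            "t_smr": [r.t_smr for r in results],
            "p_smr": [r.p_smr for r in results],
            "corrected_p": [r.corrected_p for r in results],
        }
    )


def permutation_results_frame(results: dict[str, PermutationTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "test": list(results),
            "observed": [r.observed_statistic for r in results.values()],
            "n_permutations": [r.n_permutations for r in results.values()],
            "n_exceeding": [r.n_exceeding for r in results.values()],
            "p_value": [r.p_value for r in results.values()],
            "p_report": [r.p_report for r in results.values()],
            "draw_size": [r.draw_size for r in results.values()],
        }
    )


def de_results_frame(results: Sequence[DeResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in results],
            "region": [r.region for r in results],
            "mean_case": [r.mean_case for r in results],
            "mean_control": [r.mean_control for r in results],
            "t_statistic": [r.t_statistic for r in results],
            "p_two_sided": [r.p_two_sided for r in results],
            "direction": [r.direction for r in results],
            "n_case": [r.n_case for r in results],
            "n_control": [r.n_control for r in results],
        }
    )


def cfg_ranking_frame(ranking: Sequence[tuple[int, CfgEvidence, float]]) -> pd.DataFrame:
    """Rows of (rank, evidence, total_lbf) -> ranking table."""
    rows = {
        "rank": [r for r, _, _ in ranking],
        "gene_id": [e.gene_id for _, e, _ in ranking],
        "cfg_score": [e.score for _, e, _ in ranking],
        "total_lbf": [l for _, _, l in ranking],
    }
    for ch in CFG_CHANNELS:
        rows[ch] = [int(e.channels[ch]) for _, e, _ in ranking]
    return pd.DataFrame(rows)


def write_result_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_result_table(path: str | Path) -> pd.DataFrame:
    return _read_table(path, "result table")


# ---------------------------------------------------------------------- manifest

def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path: str | Path, config, seed: int,
                   inputs: dict[str, str | Path],
                   outputs: Sequence[str] = (),
                   truth: dict | None = None) -> None:
    """Run manifest: config, seed, input checksums, stage outputs, and the
    synthetic-truth ledger when the inputs were simulated."""
    manifest = {
        "config": config.to_dict(),
        "seed": int(seed),
        "inputs": {
            name: {"path": str(p), "sha256": sha256_of(p)}
            for name, p in sorted(inputs.items())
        },
        "outputs": sorted(str(o) for o in outputs),
    }
    if truth is not None:
        manifest["truth"] = truth
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
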