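"""Readers and writers for every external format the pipeline touches.

All files are plain TSV or GMT so fixtures stay text-only and every
reader/writer pair round-trips exactly. Downstream modules never touch
files directly — they consume the validated domain types from
:mod:`netomics.types`.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .types import (
    CountsExperiment,
    GeneSet,
    GeneSetCollection,
    GwasDataset,
    Interactome,
    ValidationError,
    validate_gene_models,
)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# counts + design
# ---------------------------------------------------------------------------

def read_counts(counts_path, design_path) -> CountsExperiment:
    """Read a gene x sample count TSV and its sample design TSV.

    The counts file has a header row of sample ids and gene symbols in the
    first column; the design file is keyed by sample id and must cover every
    sample in the counts file. Design rows are aligned to counts columns.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    counts.index = counts.index.astype(str)
    design = pd.read_csv(design_path, sep="\t", index_col=0)
    design.index = design.index.astype(str)
    counts.columns = counts.columns.astype(str)
    return CountsExperiment(counts=counts, design=design)


def write_counts(exp: CountsExperiment, counts_path, design_path) -> None:
    exp.counts.to_csv(counts_path, sep="\t", index_label="gene")
    exp.design.to_csv(design_path, sep="\t", index_label="sample")


# ---------------------------------------------------------------------------
# interactome edge list
# ---------------------------------------------------------------------------

def read_edge_list(path, keep_largest_component: bool = False) -> Interactome:
    """Read a 3-column (source, target, weight) TSV into an Interactome.

    Self-loop rows are dropped (count logged); duplicate pairs keep the
    maximum weight; non-positive weight is a hard error. With
    ``keep_largest_component`` only the largest connected component is
    retained (ties: larger node count, then lexicographically smallest
    member).
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    if df.shape[1] < 3:
        raise ValidationError("edge list needs columns source, target, weight")
    triples = zip(df.iloc[:, 0], df.iloc[:, 1], df.iloc[:, 2].astype(float))
    inter = Interactome.from_edges(triples, keep_largest_component=keep_largest_component)
    dropped = getattr(inter, "n_selfloops_dropped", 0)
    if dropped:
        log.warning("dropped %d self-loop edge rows from %s", dropped, path)
    return inter


def write_edge_list(inter: Interactome, path) -> None:
    rows = sorted(
        (min(u, v), max(u, v), w)
        for u, v, w in inter.graph.edges(data="weight")
    )
    pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file (term, description, genes...; tab-separated).

    A ``SOURCE:`` prefix on the term id is parsed into the source category
    (e.g. ``GO:0031012`` -> source ``GO``); otherwise the source is
    ``custom``. Member genes are deduplicated preserving first occurrence;
    a term with an empty gene list is skipped with a warning; a duplicate
    term id is a hard error.
    """
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            term, desc = fields[0], fields[1]
            genes = [g for g in fields[2:] if g]
            if not genes:
                log.warning("%s:%d: term %r has no genes, skipped", path, lineno, term)
                continue
            source = term.split(":", 1)[0] if ":" in term else "custom"
            coll.add(GeneSet(term=term, source=source, description=desc,
                             genes=frozenset(genes)))
    return coll


def write_gmt(coll: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for term in sorted(coll.terms):
            gs = coll[term]
            fh.write("\t".join([gs.term, gs.description, *sorted(gs.genes)]) + "\n")


# ---------------------------------------------------------------------------
# gene coordinates
# ---------------------------------------------------------------------------

def read_gene_models(path, one_based_inclusive: bool = False) -> pd.DataFrame:
    """Read a gene coordinate TSV (gene, chrom, start, end).

    Internally coordinates are 0-based half-open. Set ``one_based_inclusive``
    if the file uses 1-based inclusive intervals; they are converted on read.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={"chrom": str})
    df.index = df.index.astype(str)
    if one_based_inclusive:
        df = df.assign(start=df["start"] - 1)
    return validate_gene_models(df[["chrom", "start", "end"]])


def write_gene_models(models: pd.DataFrame, path) -> None:
    models.to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# GWAS inputs
# ---------------------------------------------------------------------------

def read_gwas_dataset(dosage_path, phenotype_path, covariates_path) -> GwasDataset:
    """Read genotype dosages, binary phenotype and covariates.

    Dosage TSV: first columns ``snp``, ``chrom``, ``pos``, then one column
    per subject (values 0/1/2, empty for missing). Phenotype TSV: subject,
    phenotype. Covariates TSV: subject plus numeric columns.
    """
    dos = pd.read_csv(dosage_path, sep="\t", index_col=0)
    dos.index = dos.index.astype(str)
    snps = dos[["chrom", "pos"]].copy()
    snps["chrom"] = snps["chrom"].astype(str)
    dosage = dos.drop(columns=["chrom", "pos"]).astype(float)
    pheno = pd.read_csv(phenotype_path, sep="\t", index_col=0).iloc[:, 0]
    pheno.index = pheno.index.astype(str)
    covs = pd.read_csv(covariates_path, sep="\t", index_col=0)
    covs.index = covs.index.astype(str)
    pheno = pheno.loc[list(dosage.columns)]
    covs = covs.loc[list(dosage.columns)]
    return GwasDataset(snps=snps, dosage=dosage, phenotype=pheno, covariates=covs)


def write_gwas_dataset(data: GwasDataset, dosage_path, phenotype_path,
                       covariates_path) -> None:
    out = pd.concat([data.snps, data.dosage], axis=1)
    out.to_csv(dosage_path, sep="\t", index_label="snp")
    data.phenotype.to_frame("phenotype").to_csv(
        phenotype_path, sep="\t", index_label="subject")
    data.covariates.to_csv(covariates_path, sep="\t", index_label="subject")


def read_snp_summary(path) -> pd.DataFrame:
    """Read precomputed per-SNP summary statistics (snp, chr, pos, p[, beta, se])."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={"chrom": str})
    df.index = df.index.astype(str)
    if "p" not in df.columns:
        raise ValidationError("summary statistics need a 'p' column")
    if ((df["p"] <= 0) | (df["p"] > 1)).any():
        raise ValidationError("SNP p-values must lie in (0, 1]")
    return df


def write_snp_summary(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="snp")


# ---------------------------------------------------------------------------
# propagation outputs (Cytoscape-loadable node/edge tables)
# ---------------------------------------------------------------------------

def write_network_tables(result: pd.DataFrame, inter: Interactome,
                         out_prefix, k_column: str = "proximal") -> tuple[Path, Path]:
    """Write node and edge TSVs for the proximal network.

    ``result`` is a per-gene table with at least columns ``score``, ``z``,
    ``rank``, ``gene_type`` and a boolean membership column ``k_column``.
    The node table contains the proximal set sorted by rank then symbol;
    the edge table is the induced edge list over that set, rows sorted so
    output is byte-stable.
    """
    out_prefix = Path(out_prefix)
    members = result.index[result[k_column].astype(bool)]
    nodes = result.loc[members, ["score", "z", "rank", "gene_type"]].copy()
    nodes = (
        nodes.assign(_gene=nodes.index)
        .sort_values(["rank", "_gene"], kind="mergesort")
        .drop(columns="_gene")
    )
    node_path = out_prefix.with_name(out_prefix.name + "_nodes.tsv")
    edge_path = out_prefix.with_name(out_prefix.name + "_edges.tsv")
    nodes.to_csv(node_path, sep="\t", index_label="gene")
    mem = set(members)
    rows = sorted(
        (min(u, v), max(u, v), w)
        for u, v, w in inter.graph.edges(data="weight")
        if u in mem and v in mem
    )
    pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(
        edge_path, sep="\t", index=False
    )
    return node_path, edge_path
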