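"""Core in-memory containers shared by every pipeline stage.

All stages exchange these validated domain objects rather than raw files:
readers in :mod:`netomics.data_io` construct them, and writers serialize
them back to plain TSV/GMT so round-trips are lossless.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

GROUPS = ("CT", "LR", "NR")
TREATMENTS = ("Li-", "Li+")
TISSUES = ("fibroblast", "lymphoblast")

DESIGN_COLUMNS = ("group", "treatment", "tissue", "subject", "clone")


class ValidationError(ValueError):
    """Raised when an input object or file violates a stated invariant."""


@dataclass
class CountsExperiment:
    """Gene x sample integer count matrix plus the per-sample design.

    ``counts`` is indexed by gene symbol with sample ids as columns;
    ``design`` is indexed by sample id and carries group (CT/LR/NR),
    treatment (Li-/Li+), tissue of origin, subject and clone labels.
    Column order of ``counts`` and row order of ``design`` agree.
    """

    counts: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValidationError(f"duplicate gene symbol: {dup!r}")
        missing = [s for s in self.counts.columns if s not in self.design.index]
        if missing:
            raise ValidationError(
                f"samples in counts missing from design: {missing}"
            )
        self.design = self.design.loc[list(self.counts.columns)]
        for col in DESIGN_COLUMNS:
            if col not in self.design.columns:
                raise ValidationError(f"design lacks required column {col!r}")
            if self.design[col].isna().any():
                bad = self.design.index[self.design[col].isna()][0]
                raise ValidationError(f"sample {bad!r}: design field {col!r} missing")
        bad_group = set(self.design["group"]) - set(GROUPS)
        if bad_group:
            raise ValidationError(f"unknown group labels: {sorted(bad_group)}")
        bad_tr = set(self.design["treatment"]) - set(TREATMENTS)
        if bad_tr:
            raise ValidationError(f"unknown treatment labels: {sorted(bad_tr)}")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            frac = arr != np.floor(arr)
            if frac.any():
                g, s = np.argwhere(frac)[0]
                raise ValidationError(
                    "non-integer count at gene "
                    f"{self.counts.index[g]!r}, sample {self.counts.columns[s]!r}: "
                    f"{arr[g, s]!r}"
                )
            self.counts = self.counts.astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative count at gene {self.counts.index[g]!r}, "
                f"sample {self.counts.columns[s]!r}"
            )
        n_cond = self.design.groupby("subject")["treatment"].nunique()
        if (n_cond > 2).any():
            bad = n_cond.index[n_cond > 2][0]
            raise ValidationError(
                f"subject {bad!r} appears in more than 2 treatment conditions"
            )

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0).astype(float)

    def samples_in_cell(self, group: str, treatment: str) -> list[str]:
        """Sample ids of one design cell, e.g. (``'LR'``, ``'Li-'``)."""
        mask = (self.design["group"] == group) & (self.design["treatment"] == treatment)
        return list(self.design.index[mask])


@dataclass
class GwasDataset:
    """Per-SNP dosages, a binary phenotype and numeric covariates.

    ``snps`` is indexed by SNP id with ``chrom`` and 1-based ``pos``;
    ``dosage`` is SNP x subject with values in {0, 1, 2} or NaN for
    missing; ``phenotype`` and ``covariates`` are indexed by subject.
    """

    snps: pd.DataFrame
    dosage: pd.DataFrame
    phenotype: pd.Series
    covariates: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.snps["pos"] <= 0).any():
            raise ValidationError("SNP positions must be strictly positive")
        if not self.dosage.index.equals(self.snps.index):
            raise ValidationError("dosage rows must match the SNP table")
        if list(self.dosage.columns) != list(self.phenotype.index):
            raise ValidationError("dosage columns must match phenotype subjects")
        if not self.covariates.index.equals(self.phenotype.index):
            raise ValidationError("covariates must be indexed by the same subjects")
        vals = set(pd.unique(self.phenotype.dropna()))
        if vals != {0, 1}:
            raise ValidationError(
                f"phenotype must contain both classes 0 and 1, got {sorted(vals)}"
            )

    @property
    def subjects(self) -> list[str]:
        return list(self.phenotype.index)

    @property
    def n_subjects(self) -> int:
        return len(self.phenotype)


def validate_gene_models(models: pd.DataFrame) -> pd.DataFrame:
    """Validate a gene coordinate table (0-based half-open internally).

    Index: gene symbol (unique). Columns: ``chrom``, ``start``, ``end``.
    """
    if models.index.duplicated().any():
        dup = models.index[models.index.duplicated()][0]
        raise ValidationError(f"duplicate gene model for {dup!r}")
    if (models["start"] >= models["end"]).any():
        bad = models.index[models["start"] >= models["end"]][0]
        raise ValidationError(f"gene {bad!r}: start must be < end")
    return models


@dataclass
class Interactome:
    """Weighted undirected functional gene network.

    Wraps a :class:`networkx.Graph`; nodes are gene symbols, edges carry a
    positive ``weight`` attribute. No self-loops, no parallel edges.
    """

    graph: nx.Graph

    def __post_init__(self) -> None:
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise ValidationError(f"self-loop on node {loops[0][0]!r}")
        for u, v, w in self.graph.edges(data="weight", default=None):
            if w is None or not np.isfinite(w) or w <= 0:
                raise ValidationError(f"edge {u!r}-{v!r} has invalid weight {w!r}")

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, weighted: bool = False) -> pd.Series:
        if weighted:
            d = dict(self.graph.degree(weight="weight"))
        else:
            d = dict(self.graph.degree())
        return pd.Series(d).reindex(self.nodes)

    def subgraph(self, genes) -> "Interactome":
        """Induced subgraph with deterministic node/adjacency order.

        Built by hand: networkx subgraph views iterate their node-filter
        set, whose order is hash-randomized across processes.
        """
        keep = [g for g in genes if g in self.graph]
        keepset = set(keep)
        sub = nx.Graph()
        sub.add_nodes_from(keep)
        for u in keep:
            for v, data in self.graph[u].items():
                if v in keepset and not sub.has_edge(u, v):
                    sub.add_edge(u, v, **data)
        return Interactome(sub)

    @classmethod
    def from_edges(cls, edges, keep_largest_component: bool = False) -> "Interactome":
        """Build from an iterable of (u, v, weight) triples.

        Duplicate pairs (after canonical ordering) keep the maximum weight;
        self-loops are dropped. With ``keep_largest_component`` only the
        largest connected component survives — ties broken by node count
        then by lexicographically smallest member.
        """
        best: dict[tuple[str, str], float] = {}
        n_loops = 0
        for u, v, w in edges:
            if u == v:
                n_loops += 1
                continue
            w = float(w)
            if not np.isfinite(w) or w <= 0:
                raise ValidationError(f"edge {u!r}-{v!r}: non-positive weight {w!r}")
            key = (u, v) if u < v else (v, u)
            if key not in best or w > best[key]:
                best[key] = w
        g = nx.Graph()
        for (u, v), w in best.items():
            g.add_edge(u, v, weight=w)
        inter = cls(g)
        if keep_largest_component and g.number_of_nodes():
            comps = sorted(
                nx.connected_components(g), key=lambda c: (-len(c), min(c))
            )
            inter = inter.subgraph(sorted(comps[0]))
        inter.n_selfloops_dropped = n_loops  # type: ignore[attr-defined]
        return inter


@dataclass(frozen=True)
class GeneSet:
    term: str
    source: str
    description: str
    genes: frozenset[str]


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style), keyed by unique term id."""

    terms: dict[str, GeneSet] = field(default_factory=dict)

    def add(self, gs: GeneSet) -> None:
        if gs.term in self.terms:
            raise ValidationError(f"duplicate term id: {gs.term!r}")
        if not gs.genes:
            raise ValidationError(f"term {gs.term!r} has no member genes")
        self.terms[gs.term] = gs

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms.values())

    def __getitem__(self, term: str) -> GeneSet:
        return self.terms[term]

    def __eq__(self, other) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return self.terms == other.terms
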