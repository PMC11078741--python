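"""Community structure and function of the proximal network: Louvain
clustering, gene-set enrichment with B-H control and the seed-gene rich
factor, and hub-gene identification by induced-subgraph degree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .expression_de import bh_adjust
from .integration_overlap import hypergeom_overlap
from .types import GeneSetCollection, Interactome, ValidationError

log = logging.getLogger(__name__)


@dataclass
class ClusterPartition:
    assignment: pd.Series      # gene -> cluster id (0 = largest)
    modularity: float
    resolution: float
    seed: int
    restarts: int

    @property
    def n_clusters(self) -> int:
        return int(self.assignment.nunique()) if len(self.assignment) else 0

    def members(self, cluster: int) -> list[str]:
        return sorted(self.assignment.index[self.assignment == cluster])


def modularity(partition: dict[str, int] | pd.Series, inter: Interactome,
               gamma: float = 1.0) -> float:
    """Weighted Newman modularity with resolution gamma.

    Q = sum_c [ e_c / m - gamma * (d_c / 2m)^2 ] with e_c the intra-cluster
    weight, d_c the total weighted degree of cluster c and m the total
    edge weight.
    """
    if isinstance(partition, pd.Series):
        partition = partition.to_dict()
    g = inter.graph
    m = g.size(weight="weight")
    if m == 0:
        return 0.0
    intra: dict[int, float] = {}
    deg: dict[int, float] = {}
    for u, v, w in g.edges(data="weight", default=1.0):
        if partition[u] == partition[v]:
            intra[partition[u]] = intra.get(partition[u], 0.0) + w
    for node, d in g.degree(weight="weight"):
        c = partition[node]
        deg[c] = deg.get(c, 0.0) + d
    q = 0.0
    for c in deg:
        q += intra.get(c, 0.0) / m - gamma * (deg[c] / (2.0 * m)) ** 2
    return q


def louvain_cluster(inter: Interactome, gamma: float = 1.0, seed: int = 0,
                    restarts: int = 10) -> ClusterPartition:
    """Best-of-restarts Louvain partition, deterministic given the seed.

    Cluster ids are relabeled by decreasing size (ties: smallest member
    symbol) so cluster 0 is always the largest community.
    """
    g = inter.graph
    if g.number_of_nodes() == 0:
        return ClusterPartition(pd.Series(dtype=int), 0.0, gamma, seed, restarts)
    # run on an integer-labeled copy: set iteration over string labels is
    # hash-randomized across processes, which would break reproducibility
    names = sorted(g.nodes)
    gi = nx.relabel_nodes(g, {n: i for i, n in enumerate(names)})
    best_q = -np.inf
    best = None
    for r in range(restarts):
        comms_i = nx.community.louvain_communities(
            gi, weight="weight", resolution=gamma, seed=seed + r
        )
        comms = [{names[i] for i in c} for c in comms_i]
        part = {n: i for i, c in enumerate(comms) for n in c}
        q = modularity(part, inter, gamma)
        if q > best_q:
            best_q, best = q, comms
    order = sorted(best, key=lambda c: (-len(c), min(c)))
    assignment = pd.Series(
        {n: i for i, c in enumerate(order) for n in c}, name="cluster"
    ).sort_index()
    assignment.index.name = "gene"
    return ClusterPartition(assignment=assignment, modularity=float(best_q),
                            resolution=gamma, seed=seed, restarts=restarts)


def term_enrichment(query, collection: GeneSetCollection, background,
                    gene_types: pd.Series | None = None,
                    q_max: float = 0.05, min_overlap: int = 1,
                    require_seed_and_prioritized: bool = False,
                    rich_factor_denominator: str = "participating") -> pd.DataFrame:
    """Hypergeometric over-representation of each term in the query set.

    Terms are intersected with the background; the query must be a subset
    of the background. B-H q-values are computed across all tested terms.
    The rich factor is the fraction of seed (DE or DE/GWAB) genes among a
    term's participating genes (``rich_factor_denominator='term'`` divides
    by the term's background size instead). With
    ``require_seed_and_prioritized`` a term only passes if its
    participating genes include at least one seed (DE*) and one
    prioritized (GWAB*) gene — the pathway-style constraint.
    """
    query = set(query)
    bg = set(background)
    if not query <= bg:
        raise ValidationError("query must be a subset of the background")
    rows = []
    skipped = 0
    for gs in sorted(collection, key=lambda t: t.term):
        members = gs.genes & bg
        if not members:
            skipped += 1
            continue
        participating = sorted(gs.genes & query)
        x = len(participating)
        p = hypergeom_overlap(len(bg), len(members), len(query), x)
        types = {}
        if gene_types is not None:
            types = {g: gene_types.get(g, "network") for g in participating}
        n_seed = sum(1 for t in types.values() if t in ("DE", "DE/GWAB"))
        n_prio = sum(1 for t in types.values() if t in ("GWAB", "DE/GWAB"))
        denom = x if rich_factor_denominator == "participating" else len(members)
        rich = n_seed / denom if denom else 0.0
        rows.append(
            {
                "term": gs.term, "source": gs.source,
                "description": gs.description,
                "N_bg": len(bg), "K_term": len(members),
                "n_query": len(query), "x": x, "p": p,
                "rich_factor": rich,
                "n_seed": n_seed, "n_prioritized": n_prio,
                "genes": ";".join(participating),
                "gene_types": ";".join(f"{g}:{types.get(g, '')}"
                                       for g in participating),
            }
        )
    if skipped:
        log.info("%d terms entirely outside the background were skipped", skipped)
    if not rows:
        return pd.DataFrame(
            columns=["term", "source", "description", "N_bg", "K_term",
                     "n_query", "x", "p", "q", "rich_factor", "n_seed",
                     "n_prioritized", "significant", "genes", "gene_types"]
        ).set_index("term")
    df = pd.DataFrame(rows).set_index("term")
    df["q"] = bh_adjust(df["p"])
    df["significant"] = (df["q"] <= q_max) & (df["x"] >= min_overlap)
    if require_seed_and_prioritized:
        df["significant"] &= (df["n_seed"] >= 1) & (df["n_prioritized"] >= 1)
    return df.sort_values(["q", "p"], kind="mergesort")


def hub_genes(subgraph: Interactome, candidates,
              degree_threshold: int = 200,
              pathway_membership: dict[str, list[str]] | None = None) -> pd.DataFrame:
    """Hub-like genes: candidates whose induced-subgraph degree exceeds
    the threshold, sorted by degree descending (ties by symbol).

    Candidates not present in the subgraph are flagged rather than dropped.
    """
    deg = subgraph.degree(weighted=False)
    rows = []
    for g in sorted(set(candidates)):
        in_graph = g in deg.index
        d = int(deg[g]) if in_graph else 0
        rows.append(
            {
                "gene": g,
                "degree": d,
                "in_subgraph": in_graph,
                "hub": bool(in_graph and d > degree_threshold),
                "pathways": ";".join(sorted(pathway_membership.get(g, [])))
                if pathway_membership else "",
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["degree", "in_subgraph", "hub", "pathways"]
        ).rename_axis("gene")
    df = pd.DataFrame(rows).set_index("gene")
    df = df.assign(_g=df.index).sort_values(
        ["degree", "_g"], ascending=[False, True], kind="mergesort"
    )
    return df.drop(columns="_g")
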