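"""Random-walk-with-restart propagation of seed genes over the interactome,
degree-matched permutation significance, and proximal-network extraction.

Propagation iterates F <- alpha * F W' + (1 - alpha) * Y on the normalized
adjacency until convergence; Y places uniform restart mass on the seed
genes. Significance of a gene's stationary score is judged against R
permutations that redraw the seed set with the same degree-bin composition
as the true seeds, giving a per-gene z-score; the top-k genes by z (ties:
raw score, then symbol) plus their induced edges form the proximal network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .types import Interactome, ValidationError

log = logging.getLogger(__name__)


@dataclass
class PropagationConfig:
    alpha: float = 0.5
    tol: float = 1e-8
    max_iter: int = 10_000
    permutations: int = 1000
    degree_bins: int = 10
    k_list: tuple[int, ...] = (500, 2000)
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValidationError("restart weight alpha must lie in (0, 1)")
        if self.permutations < 100:
            raise ValidationError("need >= 100 permutations for z-scores")


@dataclass
class PropagationResult:
    """Per-gene propagation scores with permutation significance."""

    table: pd.DataFrame   # columns: score, perm_mean, perm_sd, z, rank, proximal_<k>
    seeds_used: list[str]
    seeds_dropped: list[str]
    converged: bool
    config: PropagationConfig = field(default_factory=PropagationConfig)


def normalize_adjacency(inter: Interactome, mode: str = "row_stochastic"):
    """Normalized sparse adjacency W' and its node order.

    ``row_stochastic``: D^-1 A (rows sum to 1); ``symmetric``:
    D^-1/2 A D^-1/2. Isolated nodes produce zero rows, which are flagged;
    their propagation score stays at (1 - alpha) * Y.
    """
    nodes = inter.nodes
    A = nx.to_scipy_sparse_array(inter.graph, nodelist=nodes, weight="weight",
                                 format="csr", dtype=float)
    deg = np.asarray(A.sum(axis=1)).ravel()
    isolated = deg == 0
    if isolated.any():
        log.warning("%d isolated nodes produce zero rows in W'",
                    int(isolated.sum()))
    with np.errstate(divide="ignore"):
        if mode == "row_stochastic":
            inv = np.where(deg > 0, 1.0 / deg, 0.0)
            W = sp.diags(inv) @ A
        elif mode == "symmetric":
            inv = np.where(deg > 0, 1.0 / np.sqrt(deg), 0.0)
            W = sp.diags(inv) @ A @ sp.diags(inv)
        else:
            raise ValidationError(f"unknown normalization mode {mode!r}")
    return W.tocsr(), nodes


def propagate(W, Y, alpha: float = 0.5, tol: float = 1e-8,
              max_iter: int = 10_000) -> tuple[np.ndarray, bool]:
    """Iterate F <- alpha F W' + (1-alpha) Y to the stationary scores.

    ``Y`` may be one restart vector (n,) or a stack (R, n); all rows are
    propagated simultaneously. Returns (F, converged).
    """
    single = np.ndim(Y) == 1
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    WT = W.T.tocsr()
    F = Y.copy()
    restart = (1.0 - alpha) * Y
    converged = False
    for _ in range(max_iter):
        F_new = alpha * (WT @ F.T).T + restart
        delta = np.abs(F_new - F).max()
        F = F_new
        if delta < tol:
            converged = True
            break
    if not converged:
        log.warning("propagation did not reach tol=%.1e in %d iterations",
                    tol, max_iter)
    return (F[0] if single else F), converged


def seed_vector(nodes: list[str], seeds, alpha_check: bool = True) -> tuple[np.ndarray, list[str], list[str]]:
    """Uniform restart vector over the seeds present in the graph.

    Seeds missing from the graph are dropped with a named warning; no seed
    in the graph is a hard error.
    """
    node_index = {g: i for i, g in enumerate(nodes)}
    used, dropped = [], []
    for s in sorted(set(seeds)):
        (used if s in node_index else dropped).append(s)
    if dropped:
        log.warning("seeds absent from the network, dropped: %s",
                    ", ".join(dropped))
    if not used:
        raise ValidationError("no seed gene is present in the network")
    Y = np.zeros(len(nodes))
    Y[[node_index[s] for s in used]] = 1.0 / len(used)
    return Y, used, dropped


def _degree_bins(degrees: np.ndarray, seed_idx: np.ndarray, n_bins: int):
    """Quantile bins on log(degree+1), merged until every bin can host its seeds."""
    logd = np.log(degrees + 1.0)
    edges = np.unique(np.quantile(logd, np.linspace(0, 1, n_bins + 1)))
    bins = np.clip(np.digitize(logd, edges[1:-1], right=True), 0, len(edges) - 2)
    # merge bins whose candidate pool is smaller than the seeds they must host
    while True:
        ids = np.unique(bins)
        need_merge = None
        for b in ids:
            members = np.flatnonzero(bins == b)
            n_seeds = np.isin(seed_idx, members).sum()
            if n_seeds > 0 and len(members) < max(2 * n_seeds, n_seeds + 1):
                need_merge = b
                break
        if need_merge is None or len(ids) == 1:
            break
        pos = list(ids).index(need_merge)
        neighbor = ids[pos - 1] if pos > 0 else ids[pos + 1]
        bins[bins == need_merge] = neighbor
        log.info("degree bin %d merged into %d", need_merge, neighbor)
    return bins


def degree_matched_zscores(W, nodes: list[str], F_obs: np.ndarray,
                           seeds: list[str], alpha: float = 0.5,
                           R: int = 1000, n_bins: int = 10,
                           seed: int = 0, tol: float = 1e-8,
                           max_iter: int = 10_000) -> pd.DataFrame:
    """Permutation z-scores with degree-matched random seed sets.

    Nodes are binned by quantiles of log(degree+1); each of the R
    permutations draws a random seed set with the true seeds' per-bin
    composition, propagates it, and the observed score is standardized by
    the permutation mean/sd per node (sd = 0 -> z = 0, flagged).
    """
    if R < 100:
        raise ValidationError("need >= 100 permutations")
    node_index = {g: i for i, g in enumerate(nodes)}
    seed_idx = np.array([node_index[s] for s in seeds])
    degrees = np.asarray((W != 0).sum(axis=1)).ravel().astype(float)
    bins = _degree_bins(degrees, seed_idx, n_bins)

    rng = np.random.default_rng(seed)
    n = len(nodes)
    composition = [(b, int(np.isin(seed_idx, np.flatnonzero(bins == b)).sum()))
                   for b in np.unique(bins)]
    composition = [(b, c) for b, c in composition if c > 0]
    Y = np.zeros((R, n))
    was_seed = np.zeros((R, n), dtype=bool)
    k = len(seed_idx)
    for r in range(R):
        chosen = []
        for b, c in composition:
            pool = np.flatnonzero(bins == b)
            chosen.append(rng.choice(pool, size=c, replace=False))
        idx = np.concatenate(chosen)
        Y[r, idx] = 1.0 / k
        was_seed[r, idx] = True
    F_perm, _ = propagate(W, Y, alpha=alpha, tol=tol, max_iter=max_iter)
    # a node's null moments come from the permutations in which it was NOT
    # drawn as a seed: seed status concentrates restart mass on the node
    # itself and would otherwise inflate the null mean/sd of every node
    keep = ~was_seed
    counts = keep.sum(axis=0)
    ok = counts >= 2
    safe = np.maximum(counts, 1)
    mean = (F_perm * keep).sum(axis=0) / safe
    var = (((F_perm - mean) * keep) ** 2).sum(axis=0) / np.maximum(safe - 1, 1)
    sd = np.sqrt(var)
    flagged = ~ok | (sd == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(flagged, 0.0, (F_obs - mean) / sd)
    if flagged.any():
        log.warning("%d nodes with undefined permutation null; z set to 0",
                    int(flagged.sum()))
    return pd.DataFrame(
        {"score": F_obs, "perm_mean": mean, "perm_sd": sd, "z": z,
         "z_flagged": flagged},
        index=pd.Index(nodes, name="gene"),
    )


def run_propagation(inter: Interactome, seeds,
                    config: PropagationConfig | None = None,
                    mode: str = "row_stochastic",
                    rank_by: str = "z") -> PropagationResult:
    """Full stage: normalize, propagate, permutation z, top-k flags.

    Ranking uses z by default ("significantly proximal"); ``rank_by='score'``
    ranks by raw stationary score for sensitivity analysis. Seed genes
    compete on the same ranking and stay in the proximal sets.
    """
    config = config or PropagationConfig()
    W, nodes = normalize_adjacency(inter, mode=mode)
    Y, used, dropped = seed_vector(nodes, seeds)
    F, converged = propagate(W, Y, alpha=config.alpha, tol=config.tol,
                             max_iter=config.max_iter)
    F = np.asarray(F).ravel()
    table = degree_matched_zscores(
        W, nodes, F, used, alpha=config.alpha, R=config.permutations,
        n_bins=config.degree_bins, seed=config.seed, tol=config.tol,
        max_iter=config.max_iter,
    )
    key = "z" if rank_by == "z" else "score"
    order = (
        table.assign(_g=table.index)
        .sort_values([key, "score", "_g"], ascending=[False, False, True],
                     kind="mergesort")
        .index
    )
    rank = pd.Series(np.arange(1, len(order) + 1), index=order)
    table["rank"] = rank.reindex(table.index)
    for k in config.k_list:
        kk = min(k, len(nodes))
        table[f"proximal_{k}"] = table["rank"] <= kk
    return PropagationResult(table=table, seeds_used=used,
                             seeds_dropped=dropped, converged=converged,
                             config=config)


def top_k_proximal(result: PropagationResult, inter: Interactome,
                   k: int) -> tuple[list[str], Interactome]:
    """Ranked top-k gene list and the induced subgraph."""
    t = result.table
    if k > len(t):
        k = len(t)
    sel = t[t["rank"] <= k].sort_values("rank", kind="mergesort")
    genes = list(sel.index)
    sub = inter.subgraph(genes)
    return genes, sub
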