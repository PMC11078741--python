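"""Convergence of the two evidence channels: gene-type labeling of the
proximal network and hypergeometric over-representation of the prioritized
GWAS genes among the propagation-derived network genes.

The urn is the propagation interactome: N genes in the background, K of
them on the prioritized list, n drawn into the proximal network, x shared.
The upper-tail probability P(X >= x) is computed as an exact log-space sum.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .types import ValidationError

log = logging.getLogger(__name__)

GENE_TYPES = ("DE", "DE/GWAB", "GWAB", "network")


def label_gene_types(network_genes, seed_genes, prioritized_genes) -> pd.Series:
    """Partition network genes into DE / DE+prioritized / prioritized / network.

    DE = seed only; DE/GWAB = seed and prioritized; GWAB = prioritized
    only; network = neither. The partition is exhaustive and disjoint.
    """
    seeds = set(seed_genes)
    prio = set(prioritized_genes)
    labels = {}
    for g in network_genes:
        if g in seeds and g in prio:
            labels[g] = "DE/GWAB"
        elif g in seeds:
            labels[g] = "DE"
        elif g in prio:
            labels[g] = "GWAB"
        else:
            labels[g] = "network"
    out = pd.Series(labels, name="gene_type").reindex(list(network_genes))
    out.index.name = "gene"
    return out


def hypergeom_overlap(N: int, K: int, n: int, x: int) -> float:
    """Exact upper tail P(X >= x) for X ~ Hypergeometric(N, K, n).

    Summed in log-space; never returns exactly 0 and never exceeds 1.
    ``x > min(K, n)`` is a hard error (impossible overlap).
    """
    N, K, n, x = int(N), int(K), int(n), int(x)
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValidationError(f"invalid urn: N={N}, K={K}, n={n}")
    if x < 0 or x > min(K, n):
        raise ValidationError(f"overlap x={x} outside [0, min(K, n)]")
    if x <= max(0, n + K - N):
        return 1.0  # the tail covers the whole support
    lo = max(x, n + K - N, 0)
    hi = min(K, n)
    k = np.arange(lo, hi + 1)
    log_pmf = (
        gammaln(K + 1) - gammaln(k + 1) - gammaln(K - k + 1)
        + gammaln(N - K + 1) - gammaln(n - k + 1) - gammaln(N - K - n + k + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )
    p = float(np.exp(logsumexp(log_pmf)))
    return min(max(p, np.finfo(float).tiny), 1.0)


def overlap_test(background, network_genes, prioritized_genes,
                 include=None, variant: str = "prioritized") -> dict:
    """Hypergeometric test of prioritized-gene enrichment in a network set.

    The prioritized list and the network set are both intersected with the
    background before testing (the only self-consistent urn). ``include``
    optionally extends the prioritized list (e.g. with the seed genes) for
    the seed-inclusive variant.
    """
    bg = set(background)
    net = set(network_genes) & bg
    prio = set(prioritized_genes)
    if include:
        prio = prio | set(include)
    prio &= bg
    x = len(net & prio)
    p = hypergeom_overlap(len(bg), len(prio), len(net), x)
    return {"variant": variant, "N": len(bg), "K": len(prio),
            "n": len(net), "x": x, "p": p}


def overlap_sweep(ranked_genes, prioritized_genes, background,
                  k_grid=None, seeds=None) -> pd.DataFrame:
    """-log10 hypergeometric p against proximal-network size k.

    ``ranked_genes`` is the propagation ranking (best first); for each k
    in the grid the top-k set is tested against the prioritized list. The
    values 500 and 2000 are always included (clipped to the background
    size). A grid-Bonferroni column accompanies the raw p because the
    analyst chooses k after seeing the sweep.
    """
    ranked = list(ranked_genes)
    N = len(set(background))
    if k_grid is None:
        k_grid = np.unique(np.linspace(50, min(len(ranked), N), 20, dtype=int))
    ks = sorted({int(k) for k in k_grid} | {min(500, len(ranked)), min(2000, len(ranked))})
    ks = [k for k in ks if 1 <= k <= len(ranked)]
    rows = []
    for k in ks:
        res = overlap_test(background, ranked[:k], prioritized_genes)
        if seeds is not None:
            res_s = overlap_test(background, ranked[:k], prioritized_genes,
                                 include=seeds, variant="prioritized+seeds")
            res["x_with_seeds"] = res_s["x"]
            res["p_with_seeds"] = res_s["p"]
        res["k"] = k
        rows.append(res)
    df = pd.DataFrame(rows).set_index("k")
    df["neglog10_p"] = -np.log10(df["p"])
    df["p_bonferroni"] = np.minimum(df["p"] * len(ks), 1.0)
    return df


def plot_sweep(sweep: pd.DataFrame, path) -> None:
    """Optional SVG line plot of the overlap sweep (needs matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(sweep.index, sweep["neglog10_p"], marker="o", ms=3)
    ax.set_xlabel("proximal network genes (k)")
    ax.set_ylabel("-log10 hypergeometric P")
    for k in (500, 2000):
        if k in sweep.index:
            ax.axvline(k, ls="--", color="grey", lw=0.8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
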