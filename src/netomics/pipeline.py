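"""End-to-end orchestration: DE seeds -> GWAS gene scoring -> propagation
-> overlap -> clustering/enrichment, with a config file, derived seeds,
structured logging and a markdown + JSON report.

Every stage is also runnable standalone through its module API; this
module only wires validated domain objects between stages and serializes
each stage's table so every number in the report is traceable to a TSV.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster_enrichment, data_io, expression_de, gwas_scoring
from . import integration_overlap, network_propagation, synthetic_data
from .expression_de import Contrast
from .network_propagation import PropagationConfig
from .types import ValidationError

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline parameters plus input paths and the master seed."""

    fixture_dir: str = ""
    out_dir: str = "netomics_run"
    seed: int = 0
    # DE stage
    contrasts: tuple[str, ...] = ("LR_vs_NR@Li-", "LR_vs_NR@Li+")
    cpm_threshold: float = 1.0
    p_max: float = 0.05
    lfc_min: float = 1.0
    q_max: float = 0.20
    qvalue_scope: str = "serial"
    # GWAS stage
    window_bp: int = 0
    sims: tuple[int, ...] = (1000, 10_000, 100_000)
    gwab_lambda: float = 1.0
    neighbor_cap: int = 50
    top_fraction: float = 0.05
    # propagation stage
    alpha: float = 0.5
    tol: float = 1e-8
    max_iter: int = 10_000
    permutations: int = 1000
    degree_bins: int = 10
    k_list: tuple[int, ...] = (500, 2000)
    # enrichment stage
    resolution: float = 1.0
    restarts: int = 10
    enrich_q_max: float = 0.05
    degree_threshold: int = 200

    def config_hash(self) -> str:
        """Hash of the scientific parameters (paths excluded), stable
        under key reordering."""
        payload = {k: v for k, v in asdict(self).items()
                   if k not in ("out_dir", "fixture_dir")}
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("contrasts", "sims", "k_list"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _derived_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


@dataclass
class PipelineResult:
    """In-memory handles to every stage output plus the summary dict."""

    de_results: dict[str, expression_de.DEResult]
    seeds: list[str]
    gene_scores: pd.DataFrame
    propagation: network_propagation.PropagationResult
    overlaps: pd.DataFrame
    sweep: pd.DataFrame
    partition: cluster_enrichment.ClusterPartition | None
    cluster_enrichments: dict[int, pd.DataFrame]
    pathway_enrichment: pd.DataFrame | None
    hubs: pd.DataFrame | None
    summary: dict = field(default_factory=dict)


def run_pipeline(config: RunConfig,
                 bundle: synthetic_data.FixtureBundle | None = None,
                 write_outputs: bool = True) -> PipelineResult:
    """Execute every stage on a fixture directory (or in-memory bundle).

    Stage order: DE -> gene scoring -> propagation -> overlap ->
    clustering/enrichment. Weak or empty intermediate results (no DE
    genes, no seeds in the network) degrade gracefully: downstream stages
    are skipped and flagged in the report instead of crashing.
    """
    out = Path(config.out_dir)
    if write_outputs:
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "config.yaml")
        fh = logging.FileHandler(out / "run.log")
        fh.setLevel(logging.INFO)
        logging.getLogger("netomics").addHandler(fh)
    try:
        return _run(config, bundle, write_outputs, out)
    finally:
        if write_outputs:
            logging.getLogger("netomics").removeHandler(fh)


def _run(config, bundle, write_outputs, out):
    if bundle is None:
        if not config.fixture_dir:
            raise ValidationError("no fixture_dir configured")
        bundle = synthetic_data.read_fixture(config.fixture_dir)
    seed_de, seed_gwas, seed_prop, seed_cluster = _derived_seeds(config.seed, 4)
    summary: dict = {"seed": config.seed, "config_hash": config.config_hash(),
                     "flags": []}

    # ---- stage: differential expression -------------------------------
    exp = bundle.counts
    factors = expression_de.tmm_factors(exp)
    cpm = expression_de.compute_cpm(exp, factors)
    retained = expression_de.filter_low_expression(
        cpm, threshold=config.cpm_threshold, exp=exp)
    summary["n_genes_expressed"] = exp.n_genes
    summary["n_genes_retained"] = len(retained)
    de_results: dict[str, expression_de.DEResult] = {}
    de_counts = {}
    for text in config.contrasts:
        contrast = Contrast.parse(text)
        fitted = expression_de.fit_de_model(exp, retained, contrast,
                                            factors=factors)
        filtered = expression_de.serial_filter(
            fitted, p_max=config.p_max, lfc_min=config.lfc_min,
            q_max=config.q_max, qvalue_scope=config.qvalue_scope)
        de_results[text] = filtered
        de_counts[text] = len(filtered.de_genes)
        if write_outputs:
            safe = text.replace("@", "_at_").replace(":", "_")
            filtered.table.to_csv(out / f"de_{safe}.tsv", sep="\t")
    seeds = sorted(set().union(*(r.de_genes for r in de_results.values())))
    summary["de_counts"] = de_counts
    summary["n_seed_genes"] = len(seeds)
    if len(de_results) >= 2 and write_outputs:
        venn = expression_de.compare_de_lists(
            {k: r.de_genes for k, r in de_results.items()})
        venn.to_csv(out / "de_venn.tsv", sep="\t", index=False)

    # ---- stage: GWAS gene scoring -------------------------------------
    assoc = gwas_scoring.snp_logistic_assoc(bundle.gwas)
    gene_snps = gwas_scoring.map_snps_to_genes(
        bundle.gwas.snps, bundle.gene_models, window_bp=config.window_bp)
    ld = gwas_scoring.ld_from_genotypes(bundle.gwas, gene_snps)
    snp_p = {g: assoc.loc[s, "p"].to_numpy(float)
             for g, s in gene_snps.items()}
    vegas = gwas_scoring.vegas_gene_test(snp_p, ld, sims=tuple(config.sims),
                                         seed=seed_gwas)
    scores = gwas_scoring.build_gene_score_table(
        vegas, bundle.interactome, lam=config.gwab_lambda,
        neighbor_cap=config.neighbor_cap, fraction=config.top_fraction)
    prioritized = sorted(scores.index[scores["top_boosted"]])
    prioritized_vegas = sorted(scores.index[scores["top_vegas"]])
    summary["n_snps_tested"] = int((~assoc["p"].isna()).sum())
    summary["n_genes_scored"] = len(vegas)
    summary["top_fraction_boosted"] = len(prioritized)
    summary["top_fraction_vegas"] = len(prioritized_vegas)
    if write_outputs:
        data_io.write_snp_summary(assoc, out / "snp_assoc.tsv")
        scores.to_csv(out / "gene_scores.tsv", sep="\t")

    # ---- stage: propagation -------------------------------------------
    inter = bundle.interactome
    in_graph = [s for s in seeds if s in inter.graph]
    if not in_graph:
        summary["flags"].append("no seed genes in the network; "
                                "propagation and overlap skipped")
        result = PipelineResult(de_results=de_results, seeds=seeds,
                                gene_scores=scores, propagation=None,
                                overlaps=pd.DataFrame(), sweep=pd.DataFrame(),
                                partition=None, cluster_enrichments={},
                                pathway_enrichment=None, hubs=None,
                                summary=summary)
        _finalize(result, config, out, write_outputs)
        return result
    prop_cfg = PropagationConfig(
        alpha=config.alpha, tol=config.tol, max_iter=config.max_iter,
        permutations=config.permutations, degree_bins=config.degree_bins,
        k_list=tuple(config.k_list), seed=seed_prop)
    prop = network_propagation.run_propagation(inter, seeds, prop_cfg)
    summary["n_seeds_in_network"] = len(prop.seeds_used)
    summary["seeds_dropped"] = prop.seeds_dropped

    # ---- stage: overlap -----------------------------------------------
    background = inter.nodes
    ranking = list(prop.table.sort_values("rank", kind="mergesort").index)
    overlap_rows = []
    labels_by_k = {}
    for k in config.k_list:
        kk = min(k, len(ranking))
        net_genes = ranking[:kk]
        labels = integration_overlap.label_gene_types(
            net_genes, prop.seeds_used, prioritized)
        labels_by_k[k] = labels
        res = integration_overlap.overlap_test(background, net_genes,
                                               prioritized)
        res_s = integration_overlap.overlap_test(
            background, net_genes, prioritized, include=prop.seeds_used,
            variant="prioritized+seeds")
        for r in (res, res_s):
            r["k"] = kk
            overlap_rows.append(r)
        counts = labels.value_counts()
        summary[f"network_{k}"] = {
            "n_nodes": kk,
            "n_edges": inter.subgraph(net_genes).n_edges,
            "composition": {t: int(counts.get(t, 0))
                            for t in integration_overlap.GENE_TYPES},
            "overlap_x": res["x"],
            "overlap_p": res["p"],
            "overlap_x_with_seeds": res_s["x"],
            "overlap_p_with_seeds": res_s["p"],
        }
    overlaps = pd.DataFrame(overlap_rows)
    sweep = integration_overlap.overlap_sweep(
        ranking, prioritized, background, seeds=prop.seeds_used)
    if write_outputs:
        table = prop.table.copy()
        k0 = config.k_list[0]
        table["gene_type"] = labels_by_k[k0].reindex(table.index).fillna("network")
        table.to_csv(out / "propagation.tsv", sep="\t")
        overlaps.to_csv(out / "overlap.tsv", sep="\t", index=False)
        sweep.to_csv(out / "overlap_sweep.tsv", sep="\t")
        data_io.write_network_tables(
            table.rename(columns={"score": "score"}), inter,
            out / f"network_{k0}", k_column=f"proximal_{k0}")

    # ---- stage: clustering + enrichment -------------------------------
    k0 = config.k_list[0]
    kk0 = min(k0, len(ranking))
    net_genes, subgraph = network_propagation.top_k_proximal(prop, inter, kk0)
    partition = cluster_enrichment.louvain_cluster(
        subgraph, gamma=config.resolution, seed=seed_cluster,
        restarts=config.restarts)
    gene_types = labels_by_k[k0]
    coll = bundle.gene_sets
    cluster_enr = {}
    n_terms = 0
    for c in sorted(partition.assignment.unique()):
        members = partition.members(c)
        enr = cluster_enrichment.term_enrichment(
            members, coll, background, gene_types=gene_types,
            q_max=config.enrich_q_max)
        cluster_enr[int(c)] = enr
        n_terms += int(enr["significant"].sum())
        if write_outputs:
            enr.to_csv(out / f"enrichment_cluster{c}.tsv", sep="\t")
    pathway_enr = cluster_enrichment.term_enrichment(
        net_genes, coll, background, gene_types=gene_types,
        q_max=config.enrich_q_max, require_seed_and_prioritized=True)
    sig_terms = pathway_enr[pathway_enr["significant"]]
    candidates = sorted(
        {g for genes in sig_terms["genes"] for g in genes.split(";") if g})
    membership: dict[str, list[str]] = {}
    for term, row in sig_terms.iterrows():
        for g in row["genes"].split(";"):
            if g:
                membership.setdefault(g, []).append(term)
    hubs = cluster_enrichment.hub_genes(
        subgraph, candidates, degree_threshold=config.degree_threshold,
        pathway_membership=membership)
    summary["n_clusters"] = partition.n_clusters
    summary["modularity"] = round(partition.modularity, 4)
    summary["n_enriched_terms_clusters"] = n_terms
    summary["n_enriched_pathways"] = int(sig_terms.shape[0])
    summary["n_hub_genes"] = int(hubs["hub"].sum())
    if not seeds:
        summary["flags"].append("no DE genes called")
    if write_outputs:
        partition.assignment.to_frame().to_csv(out / "clusters.tsv", sep="\t")
        pathway_enr.to_csv(out / "enrichment_pathways.tsv", sep="\t")
        hubs.to_csv(out / "hubs.tsv", sep="\t")

    result = PipelineResult(
        de_results=de_results, seeds=seeds, gene_scores=scores,
        propagation=prop, overlaps=overlaps, sweep=sweep,
        partition=partition, cluster_enrichments=cluster_enr,
        pathway_enrichment=pathway_enr, hubs=hubs, summary=summary)
    _finalize(result, config, out, write_outputs)
    return result


def _finalize(result: PipelineResult, config: RunConfig, out: Path,
              write_outputs: bool) -> None:
    if not write_outputs:
        return
    with open(out / "summary.json", "w") as fh:
        json.dump(result.summary, fh, indent=2, sort_keys=True, default=str)
    with open(out / "report.md", "w") as fh:
        fh.write(render_report(result, config))


def render_report(result: PipelineResult, config: RunConfig) -> str:
    """Markdown report; every number it shows is also in a stage TSV."""
    s = result.summary
    lines = ["# netomics pipeline report", ""]
    lines += [f"- master seed: {s['seed']}",
              f"- config hash: {s['config_hash']}", ""]
    lines += ["## Differential expression",
              f"- expressed genes: {s['n_genes_expressed']}; retained after "
              f"CPM filter: {s['n_genes_retained']}"]
    for k, v in s.get("de_counts", {}).items():
        lines.append(f"- {k}: {v} DE genes")
    lines.append(f"- seed genes (union): {s['n_seed_genes']}")
    lines += ["", "## GWAS gene scoring",
              f"- SNPs tested: {s.get('n_snps_tested', 0)}",
              f"- genes scored: {s.get('n_genes_scored', 0)}",
              f"- top-fraction boosted list: {s.get('top_fraction_boosted', 0)}"
              f" genes; empirical-test list: {s.get('top_fraction_vegas', 0)}"]
    for k in config.k_list:
        key = f"network_{k}"
        if key in s:
            net = s[key]
            comp = net["composition"]
            lines += ["", f"## Proximal network (top {net['n_nodes']})",
                      f"- edges: {net['n_edges']}",
                      "- composition: " + ", ".join(
                          f"{t}: {comp[t]}" for t in comp),
                      f"- overlap with prioritized genes: x = {net['overlap_x']}"
                      f", hypergeometric p = {net['overlap_p']:.3e}",
                      f"- including seeds: x = {net['overlap_x_with_seeds']}, "
                      f"p = {net['overlap_p_with_seeds']:.3e}"]
    if result.partition is not None:
        lines += ["", "## Clusters and enrichment",
                  f"- clusters: {s.get('n_clusters', 0)} "
                  f"(modularity {s.get('modularity', 0)})",
                  f"- significantly enriched terms across clusters: "
                  f"{s.get('n_enriched_terms_clusters', 0)}",
                  f"- enriched pathway-style terms: "
                  f"{s.get('n_enriched_pathways', 0)}",
                  f"- hub genes: {s.get('n_hub_genes', 0)}"]
    if s.get("flags"):
        lines += ["", "## Flags"] + [f"- {f}" for f in s["flags"]]
    lines.append("")
    return "\n".join(lines)
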