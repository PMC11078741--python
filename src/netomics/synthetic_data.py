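"""Synthetic fixtures with a single planted functional module visible to
both omics channels.

The generator emulates the statistical design the pipeline expects: a
scale-free interactome with one densified module M; an RNA-seq experiment
of 3 groups (6 CT / 6 LR / 5 NR), each subject measured untreated (Li-)
and lithium-treated (Li+), with negative-binomial counts and a small set
of large-effect DE genes concentrated in M; and a case/control GWAS
(n = 256) whose causal genes are likewise enriched in M. All truth is
serialized alongside the fixture, and everything is deterministic under
the master seed.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import multivariate_normal, norm

from . import data_io
from .types import CountsExperiment, GwasDataset, Interactome, ValidationError

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# parameter presets
# ---------------------------------------------------------------------------

@dataclass
class GeneratorParams:
    """All generator knobs; defaults are the study-like conditions."""

    # interactome
    n_network_genes: int = 5000
    attachment_m: int = 5
    module_size: int = 150
    p_in: float = 0.10
    # RNA-seq
    n_expressed_genes: int = 2000
    n_ct: int = 6
    n_lr: int = 6
    n_nr: int = 5
    n_de: int = 40
    n_de_in_module: int = 30
    log2fc: float = 2.0
    dispersion: float = 0.1
    baseline_log_mean: float = float(np.log(60.0))
    baseline_log_sd: float = 1.3
    subject_log_sd: float = 0.2
    depth_log_sd: float = 0.3
    tissue_shift: float = 0.4
    tissue_gene_fraction: float = 0.05
    # GWAS
    n_subjects: int = 256
    n_gwas_genes: int = 1200
    snps_per_gene: int = 8
    maf_low: float = 0.05
    maf_high: float = 0.5
    ld_rho: float = 0.8
    n_causal: int = 60
    n_causal_in_module: int = 45
    n_causal_snps_per_gene: int = 4
    beta: float = 0.4
    # gene sets
    n_terms: int = 100
    term_size_low: int = 20
    term_size_high: int = 200
    planted_jaccard: float = 0.8


def preset(name: str) -> GeneratorParams:
    """Named parameter presets: ``paperlike`` (default study-like scale)
    and ``small`` (reduced sizes for fast end-to-end calibration runs;
    effect sizes, dispersions and LD are unchanged)."""
    if name == "paperlike":
        return GeneratorParams()
    if name == "small":
        return GeneratorParams(
            n_network_genes=1500, attachment_m=4, module_size=80, p_in=0.12,
            n_expressed_genes=1000, n_de=30, n_de_in_module=24,
            n_gwas_genes=400, snps_per_gene=4,
            n_causal=40, n_causal_in_module=30,
            n_terms=60, term_size_low=10, term_size_high=100,
        )
    raise ValidationError(f"unknown preset {name!r}")


@dataclass
class SyntheticTruth:
    module: list[str]
    de_genes: dict[str, float]          # gene -> true log2FC (LR vs NR)
    causal_genes: list[str]
    causal_snps: dict[str, float]       # snp -> true beta
    params: dict
    seed: int


@dataclass
class FixtureBundle:
    interactome: Interactome
    counts: CountsExperiment
    gwas: GwasDataset
    gene_models: pd.DataFrame
    gene_sets: "object"
    truth: SyntheticTruth


# ---------------------------------------------------------------------------
# interactome
# ---------------------------------------------------------------------------

def _gene_names(n: int) -> list[str]:
    width = len(str(n))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def simulate_interactome(n_genes: int = 5000, attachment_m: int = 5,
                         module_size: int = 150, p_in: float = 0.10,
                         seed: int = 0) -> tuple[Interactome, list[str]]:
    """Scale-free backbone plus a densified module.

    A Barabasi-Albert graph provides the heavy-tailed degree backbone;
    each within-module gene pair then gains an extra edge with probability
    ``p_in``, planting a community visible to propagation and clustering.
    All weights are 1.0.
    """
    if module_size >= n_genes:
        raise ValidationError("module must be smaller than the gene universe")
    rng = np.random.default_rng(seed)
    g = nx.barabasi_albert_graph(n_genes, attachment_m,
                                 seed=int(rng.integers(2**31)))
    names = _gene_names(n_genes)
    g = nx.relabel_nodes(g, dict(enumerate(names)))
    module = sorted(str(g) for g in rng.choice(names, size=module_size, replace=False))
    if p_in > 0:
        mod = np.array(module)
        iu, ju = np.triu_indices(module_size, k=1)
        hit = rng.random(iu.size) < p_in
        for a, b in zip(mod[iu[hit]], mod[ju[hit]]):
            g.add_edge(str(a), str(b))
    nx.set_edge_attributes(g, 1.0, "weight")
    return Interactome(g), module


# ---------------------------------------------------------------------------
# RNA-seq counts
# ---------------------------------------------------------------------------

def simulate_counts(gene_universe: list[str], module: list[str],
                    params: GeneratorParams, seed: int = 0,
                    null: bool = False) -> tuple[CountsExperiment, dict[str, float]]:
    """NB counts for the 6 CT / 6 LR / 5 NR paired-treatment design.

    Expressed genes are drawn from the interactome universe (the module is
    always included). The planted DE effect is applied to the LR group in
    both treatment conditions, so the LR-vs-NR contrast carries the same
    signal with and without lithium. Subject baselines are shared between
    a subject's paired samples; library depths vary log-normally; a
    tissue-of-origin shift affects a small gene fraction in lymphoblast-
    derived subjects. ``null`` zeroes the DE effect (matched no-signal
    fixture).
    """
    p = params
    rng = np.random.default_rng(seed)
    # the expressed-gene universe is a uniform draw from the interactome;
    # only the planted DE genes are forced in (they are expressed by
    # construction). Under the null nothing is forced, so neither channel
    # over-represents the module and the integration null stays calibrated.
    de_mod = sorted(str(g) for g in rng.choice(module, size=p.n_de_in_module, replace=False))
    non_module = [g for g in gene_universe if g not in set(module)]
    de_off = sorted(str(g) for g in rng.choice(
        non_module, size=p.n_de - p.n_de_in_module, replace=False))
    de_genes = de_mod + de_off
    signs = rng.choice([-1.0, 1.0], size=len(de_genes))
    lfc = {g: float(s * p.log2fc) for g, s in zip(de_genes, signs)}
    if null:
        lfc = {g: 0.0 for g in de_genes}
    forced = [] if null else list(de_genes)
    pool = [g for g in gene_universe if g not in set(forced)]
    n_extra = p.n_expressed_genes - len(forced)
    if n_extra < 0:
        raise ValidationError("n_expressed_genes smaller than the DE set")
    genes = sorted(forced + [str(g) for g in rng.choice(pool, size=n_extra, replace=False)])
    if null:
        # DE slots keep zero effect but must live in the universe
        lfc = {str(g): 0.0 for g in rng.choice(genes, size=p.n_de, replace=False)}

    subjects = ([f"CT{i:02d}" for i in range(1, p.n_ct + 1)]
                + [f"LR{i:02d}" for i in range(1, p.n_lr + 1)]
                + [f"NR{i:02d}" for i in range(1, p.n_nr + 1)])
    group = {s: s[:2] for s in subjects}
    tissue = {s: ("fibroblast" if rng.random() < 0.6 else "lymphoblast")
              for s in subjects}

    base = np.exp(rng.normal(p.baseline_log_mean, p.baseline_log_sd,
                             size=len(genes)))
    tissue_genes = rng.choice(len(genes),
                              size=int(p.tissue_gene_fraction * len(genes)),
                              replace=False)
    gene_idx = {g: i for i, g in enumerate(genes)}

    design_rows = []
    cols = {}
    for s in subjects:
        subj_eff = np.exp(rng.normal(0.0, p.subject_log_sd, size=len(genes)))
        for treatment in ("Li-", "Li+"):
            sample = f"{s}.{'minus' if treatment == 'Li-' else 'plus'}"
            mean = base * subj_eff
            if group[s] == "LR":
                for g2, l in lfc.items():
                    mean[gene_idx[g2]] = mean[gene_idx[g2]] * 2.0 ** l
            if tissue[s] == "lymphoblast":
                mean[tissue_genes] = mean[tissue_genes] * np.exp(p.tissue_shift)
            depth = np.exp(rng.normal(0.0, p.depth_log_sd))
            mu = mean * depth
            r = 1.0 / p.dispersion
            lam = rng.gamma(shape=r, scale=mu / r)
            counts = rng.poisson(lam)
            cols[sample] = counts
            design_rows.append(
                {"sample": sample, "group": group[s], "treatment": treatment,
                 "tissue": tissue[s], "subject": s, "clone": f"{s}.c1"}
            )
    counts = pd.DataFrame(cols, index=pd.Index(genes, name="gene"))
    design = pd.DataFrame(design_rows).set_index("sample")
    return CountsExperiment(counts=counts, design=design), lfc


# ---------------------------------------------------------------------------
# GWAS
# ---------------------------------------------------------------------------

_TETRA_CACHE: dict[tuple[float, float], float] = {}


def _latent_rho(target: float, maf: float) -> float:
    """Latent Gaussian correlation producing allele-indicator correlation
    ``target`` at minor-allele frequency ``maf`` (tetrachoric inversion)."""
    key = (round(target, 3), round(maf, 2))
    if key in _TETRA_CACHE:
        return _TETRA_CACHE[key]
    t = norm.ppf(maf)

    def phi_corr(rho):
        p11 = multivariate_normal(mean=[0, 0],
                                  cov=[[1, rho], [rho, 1]]).cdf([t, t])
        return (p11 - maf**2) / (maf * (1 - maf)) - target

    hi = 0.999
    if phi_corr(hi) < 0:
        rho = hi
    else:
        rho = brentq(phi_corr, 0.0, hi, xtol=1e-4)
    _TETRA_CACHE[key] = float(rho)
    return float(rho)


def simulate_gwas(gene_universe: list[str], module: list[str],
                  params: GeneratorParams, seed: int = 0,
                  null: bool = False):
    """Case/control GWAS over a gene subset enriched for the module.

    Dosages arise from two latent AR(1) Gaussian haplotypes per gene block,
    thresholded at the minor-allele frequency; the latent correlation is
    calibrated (tetrachoric inversion) so the realized adjacent dosage
    correlation matches ``ld_rho``. The phenotype follows a logistic model
    on the centered causal dosages with the intercept tuned to ~50%
    prevalence; age, sex and three PC-like covariates are generated with
    null effects. ``null`` zeroes the causal effects.

    Returns (GwasDataset, gene-model table, truth dict).
    """
    p = params
    rng = np.random.default_rng(seed)
    # genotyped-gene universe: uniform draw, with only the causal genes
    # forced in (mirrors simulate_counts; keeps the null calibrated)
    causal_mod = sorted(str(g) for g in rng.choice(
        module, size=p.n_causal_in_module, replace=False))
    non_module = [g for g in gene_universe if g not in set(module)]
    causal_off = sorted(str(g) for g in rng.choice(
        non_module, size=p.n_causal - p.n_causal_in_module, replace=False))
    causal = causal_mod + causal_off
    forced = [] if null else list(causal)
    pool = [g for g in gene_universe if g not in set(forced)]
    n_extra = p.n_gwas_genes - len(forced)
    if n_extra < 0:
        raise ValidationError("n_gwas_genes smaller than the causal set")
    genes = sorted(forced + [str(g) for g in rng.choice(pool, size=n_extra, replace=False)])
    if null:
        causal = []

    gene_len = 5000
    spacing = 10_000
    models = pd.DataFrame(
        {
            "chrom": "1",
            "start": [i * spacing for i in range(len(genes))],
            "end": [i * spacing + gene_len for i in range(len(genes))],
        },
        index=pd.Index(genes, name="gene"),
    )

    snp_ids, snp_pos, dosage_rows = [], [], []
    causal_snps: dict[str, float] = {}
    lp = np.zeros(p.n_subjects)
    for gi, gene in enumerate(genes):
        m = p.snps_per_gene
        # tightly linked SNPs share similar allele frequencies; a common
        # per-gene base MAF with small jitter keeps the target dosage
        # correlation attainable (binary correlations shrink when margins
        # differ)
        base_maf = rng.uniform(p.maf_low, p.maf_high)
        mafs = np.clip(base_maf * (1 + rng.normal(0, 0.08, size=m)),
                       p.maf_low, p.maf_high)
        rho_lat = _latent_rho(p.ld_rho, float(np.mean(mafs))) if m > 1 else 0.0
        dos = np.zeros((m, p.n_subjects))
        for hap in range(2):
            z = np.empty((m, p.n_subjects))
            z[0] = rng.standard_normal(p.n_subjects)
            for j in range(1, m):
                z[j] = (rho_lat * z[j - 1]
                        + np.sqrt(1 - rho_lat**2) * rng.standard_normal(p.n_subjects))
            dos += (z < norm.ppf(mafs)[:, None]).astype(float)
        start = int(models.loc[gene, "start"])
        pos = start + np.linspace(0.5, m - 0.5, m) * (gene_len / m)
        ids = [f"{gene}_snp{j+1}" for j in range(m)]
        snp_ids.extend(ids)
        snp_pos.extend(int(q) + 1 for q in pos)  # 1-based
        dosage_rows.append(dos)
        if gene in causal and not null:
            # the common variants carry the causal effects (power at the
            # study's sample size comes from common alleles)
            k = min(p.n_causal_snps_per_gene, m)
            idx = np.argsort(-mafs)[:k]
            for j in sorted(idx):
                causal_snps[ids[j]] = p.beta
                lp = lp + p.beta * (dos[j] - dos[j].mean())
    dosage = np.vstack(dosage_rows)

    subjects = [f"S{i:03d}" for i in range(1, p.n_subjects + 1)]

    def prevalence(c):
        return expit(lp - c).mean() - 0.5

    c0 = brentq(prevalence, -20, 20) if np.ptp(lp) > 0 else 0.0
    prob = expit(lp - c0)
    y = rng.binomial(1, prob)
    if y.min() == y.max():  # degenerate draw; force both classes
        y[0] = 1 - y[0]

    covs = pd.DataFrame(
        {
            "age": rng.normal(45, 10, p.n_subjects),
            "sex": rng.binomial(1, 0.5, p.n_subjects).astype(float),
            "PC1": rng.standard_normal(p.n_subjects),
            "PC2": rng.standard_normal(p.n_subjects),
            "PC3": rng.standard_normal(p.n_subjects),
        },
        index=pd.Index(subjects, name="subject"),
    )
    snps = pd.DataFrame({"chrom": "1", "pos": snp_pos},
                        index=pd.Index(snp_ids, name="snp"))
    data = GwasDataset(
        snps=snps,
        dosage=pd.DataFrame(dosage, index=snps.index, columns=subjects),
        phenotype=pd.Series(y, index=subjects, name="phenotype"),
        covariates=covs,
    )
    truth = {"causal_genes": causal if not null else [],
             "causal_snps": causal_snps}
    return data, models, truth


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------

def simulate_gmt(gene_universe: list[str], module: list[str],
                 params: GeneratorParams, seed: int = 0):
    """Decoy terms plus one planted term overlapping the module.

    The planted term has the module's size and shares k = 2mj/(1+j) genes
    with it, which realizes the configured Jaccard index j; decoys are
    uniform draws with sizes in the configured bounds.
    """
    from .types import GeneSet, GeneSetCollection

    p = params
    rng = np.random.default_rng(seed)
    coll = GeneSetCollection()
    m = len(module)
    j = p.planted_jaccard
    k = int(round(2 * m * j / (1 + j))) if j > 0 else 0
    in_mod = sorted(str(g) for g in rng.choice(module, size=k, replace=False)) if k else []
    pool = [g for g in gene_universe if g not in set(module)]
    noise = sorted(str(g) for g in rng.choice(pool, size=m - k, replace=False))
    coll.add(GeneSet(term="PLANTED:module", source="PLANTED",
                     description="planted module term",
                     genes=frozenset(in_mod + noise)))
    for i in range(1, p.n_terms):
        size = int(rng.integers(p.term_size_low, p.term_size_high + 1))
        members = rng.choice(gene_universe, size=size, replace=False)
        coll.add(GeneSet(term=f"DECOY:{i:03d}", source="DECOY",
                         description=f"decoy term {i}",
                         genes=frozenset(members)))
    return coll


# ---------------------------------------------------------------------------
# bundle + fixture I/O
# ---------------------------------------------------------------------------

def simulate_bundle(seed: int = 0, params: GeneratorParams | None = None,
                    null: bool = False) -> FixtureBundle:
    """Generate the complete multi-omics fixture from one master seed.

    Stage seeds are spawned deterministically from the master seed; with
    ``null`` both planted effects (DE log2FC and GWAS beta) are zero while
    everything else is identical in distribution.
    """
    params = params or GeneratorParams()
    ss = np.random.SeedSequence(seed)
    s_net, s_cnt, s_gwas, s_gmt = [int(c.generate_state(1)[0] % (2**31))
                                   for c in ss.spawn(4)]
    inter, module = simulate_interactome(
        params.n_network_genes, params.attachment_m, params.module_size,
        params.p_in, seed=s_net,
    )
    universe = inter.nodes
    counts, lfc = simulate_counts(universe, module, params, seed=s_cnt,
                                  null=null)
    gwas, models, gtruth = simulate_gwas(universe, module, params,
                                         seed=s_gwas, null=null)
    gmt = simulate_gmt(universe, module, params, seed=s_gmt)
    truth = SyntheticTruth(
        module=list(module),
        de_genes={g: l for g, l in lfc.items() if l != 0.0} if not null
        else {g: 0.0 for g in lfc},
        causal_genes=list(gtruth["causal_genes"]),
        causal_snps=dict(gtruth["causal_snps"]),
        params=asdict(params),
        seed=seed,
    )
    return FixtureBundle(interactome=inter, counts=counts, gwas=gwas,
                         gene_models=models, gene_sets=gmt, truth=truth)


def _to_builtin(obj):
    """Recursively coerce numpy scalars/strings for YAML serialization."""
    if isinstance(obj, dict):
        return {_to_builtin(k): _to_builtin(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_builtin(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


FIXTURE_FILES = (
    "counts.tsv", "design.tsv", "edges.tsv", "gene_models.tsv",
    "dosage.tsv", "phenotype.tsv", "covariates.tsv", "genesets.gmt",
    "truth.yaml",
)


def write_fixture(bundle: FixtureBundle, out_dir, force: bool = False) -> Path:
    """Write the complete on-disk dataset plus a truth/parameter manifest.

    The manifest records every generator parameter, the master seed and a
    SHA-256 over all data files, so identical seeds yield identical
    manifest hashes.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise ValidationError(f"output dir {out} is not empty (use force)")
    out.mkdir(parents=True, exist_ok=True)
    data_io.write_counts(bundle.counts, out / "counts.tsv", out / "design.tsv")
    data_io.write_edge_list(bundle.interactome, out / "edges.tsv")
    data_io.write_gene_models(bundle.gene_models, out / "gene_models.tsv")
    data_io.write_gwas_dataset(bundle.gwas, out / "dosage.tsv",
                               out / "phenotype.tsv", out / "covariates.tsv")
    data_io.write_gmt(bundle.gene_sets, out / "genesets.gmt")
    with open(out / "truth.yaml", "w") as fh:
        yaml.safe_dump(
            _to_builtin(
                {
                    "module": bundle.truth.module,
                    "de_genes": bundle.truth.de_genes,
                    "causal_genes": bundle.truth.causal_genes,
                    "causal_snps": bundle.truth.causal_snps,
                    "seed": bundle.truth.seed,
                }
            ),
            fh, sort_keys=True,
        )
    h = hashlib.sha256()
    for name in FIXTURE_FILES:
        h.update(name.encode())
        h.update((out / name).read_bytes())
    manifest = _to_builtin({
        "seed": bundle.truth.seed,
        "params": bundle.truth.params,
        "files": list(FIXTURE_FILES),
        "sha256": h.hexdigest(),
    })
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return out


def read_fixture(fixture_dir) -> FixtureBundle:
    """Load a written fixture back into a bundle (truth included)."""
    d = Path(fixture_dir)
    counts = data_io.read_counts(d / "counts.tsv", d / "design.tsv")
    inter = data_io.read_edge_list(d / "edges.tsv")
    models = data_io.read_gene_models(d / "gene_models.tsv")
    gwas = data_io.read_gwas_dataset(d / "dosage.tsv", d / "phenotype.tsv",
                                     d / "covariates.tsv")
    gmt = data_io.read_gmt(d / "genesets.gmt")
    with open(d / "truth.yaml") as fh:
        t = yaml.safe_load(fh)
    with open(d / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    truth = SyntheticTruth(
        module=t["module"], de_genes=t["de_genes"],
        causal_genes=t["causal_genes"], causal_snps=t["causal_snps"],
        params=manifest["params"], seed=t["seed"],
    )
    return FixtureBundle(interactome=inter, counts=counts, gwas=gwas,
                         gene_models=models, gene_sets=gmt, truth=truth)
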