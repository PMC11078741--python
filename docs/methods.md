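# Methods

This note records the models, the defaults and the numerical choices
behind each pipeline stage, what the synthetic generator does and does not
emulate, and the known limitations.

## Differential expression

Counts are modeled per gene as negative binomial,
var(y) = μ + φμ², with a log-linear mean

    log μ = Xβ + log(library size × TMM factor).

TMM factors follow the doubly-trimmed, precision-weighted mean of M-values
(trim 30% per tail on M, 5% per tail on A; reference sample = the one whose
75th-percentile count fraction is closest to the mean of those fractions,
ties broken by sample order; factors rescaled to geometric mean 1). The
implementation agrees with edgeR's `calcNormFactors` to within 2% on
shifted-library simulations (cross-checked in the test suite via Rscript).

Designs: across-group contrasts (e.g. responders vs non-responders at one
treatment) use intercept + arm + tissue-of-origin; within-group (treated vs
untreated) contrasts use subject fixed effects plus treatment, because the
paired samples share a subject baseline; an interaction design
(group × treatment) is available for testing whether the treatment effect
differs between groups.

Dispersion: a Poisson fit provides method-of-moments genewise estimates
(df-corrected by n/(n−p), clipped to [1e-6, 10]); each gene's φ is shrunk
toward the across-gene median with weight 0.8 on the common value. This
pooling is what makes 11–12-sample designs usable at all; it assumes
dispersion is roughly exchangeable across genes.

Testing: the likelihood-ratio statistic for the contrast coefficient is
referred to an F(1, n − p) distribution rather than χ²(1). At these sample
sizes the asymptotic χ² reference is measurably anticonservative in the far
tail (observed ~2× the nominal rate below p = 0.005 in null simulations),
which silently inflates the realized FDR; the F reference — in the spirit
of quasi-likelihood small-sample corrections — restores far-tail
calibration while keeping the type-I rate at p < 0.05 inside [0.03, 0.07].

log2FC is the fitted contrast coefficient divided by log 2. A small ridge
(0.01 on non-intercept coefficients) keeps the estimate finite when one arm
is all zeros; no ad-hoc pseudo-counts are used. Non-converged genes are
flagged and assigned p = 1.

Serial filters: a gene is DE iff CPM > 1 in at least a design-cell-sized
quorum of samples, p < 0.05, |log2FC| ≥ 1, and B-H q ≤ 0.20. By default q
is computed over the genes surviving the earlier gates, mirroring the
serial-filter semantics; note that B-H's FDR guarantee formally holds only
for the genome-wide adjustment, which is available as
`qvalue_scope="genome_wide"` and is the scope under which the planted-truth
FDR test asserts control. The serial scope is more permissive by
construction — it reproduces the filtering behavior, not an FDR theorem.

qPCR utilities: relative fold change by 2^−ΔΔCt with replicate Ct values
aggregated by arithmetic mean on the Ct scale; the SEM of ΔΔCt combines
both arms' replicate variances and propagates to the fold-change scale as
FC·ln2·SEM. Concordance between platforms is the squared Pearson
correlation with a t-based p-value on n − 2 df.

## GWAS gene scoring

Per-SNP association is a logistic regression of case status on dosage plus
covariates (age, sex, three PCs by default), fit by Newton–Raphson
batched across SNPs (all SNPs share the covariate block). Missing dosages
are mean-imputed (missingness ≥ 10% is logged); monomorphic SNPs are
excluded; separation (|β| > 15 or exploding SE) is flagged with p = 1.
Coefficients and standard errors match `statsmodels.Logit` to 1e-5
(dual-route test).

Gene-based test: SNPs map to genes whose 0-based half-open interval
(± window, default 0 bp) contains them; multi-assignment is allowed. The
observed statistic is T = Σⱼ [Φ⁻¹(pⱼ/2)]²; the null draws v ~ MVN(0, Σ)
with Σ the dosage correlation matrix repaired to PSD (eigenvalues clipped
at 0, rescaled to unit diagonal), and the empirical p is
(1 + #{Σv² ≥ T}) / (1 + S) — never exactly 0. The simulation count
escalates 10³ → 10⁴ → 10⁵ while the interim estimate stays below
0.1 → 0.01, so only promising genes pay for precision. Per-gene RNG
streams are spawned deterministically from the stage seed.

Network boost: with s_i = −log₁₀(gene p), the boosted score is

    B_i = s_i + λ · (Σ_{j∈N_c(i)} w_ij s_j) / (Σ_{j∈N_c(i)} w_ij),

where N_c(i) is the up-to-50 strongest-weight neighbors (ties by symbol)
and unscored neighbors contribute s = 0. λ defaults to 1 (own evidence and
neighborhood evidence weighted equally); isolated genes keep their score
exactly. The score table — and hence the "top 5%" denominator — contains
the genes with at least one mapped SNP: the boost re-ranks the GWAS gene
list using the network, it does not mint association evidence for genes
that were never tested. Top-fraction selection takes ⌈fraction × n⌉ genes
by descending score, ties broken by raw score then symbol.

## Network propagation

The interactome adjacency is row-normalized (W′ = D⁻¹A; a symmetric
D^(−1/2)AD^(−1/2) variant exists) and the walk iterates
F ← αFW′ + (1−α)Y to a 1e-8 sup-norm fixed point, where Y spreads unit
restart mass uniformly over the seed genes present in the graph (absent
seeds are dropped by name; no seeds at all is a hard error). α defaults to
0.5 — an even split between diffusion and restart; the iterative solution
equals the dense closed form (1−α)Y(I−αW′)⁻¹ to 1e-8 (tested on random
graphs) and conserves total mass in row-stochastic mode.

Significance: nodes are binned into 10 quantile bins of log(degree+1);
bins too small to host their seeds are merged with a neighbor. Each of R =
1000 permutations draws a seed set with the true seeds' per-bin
composition, and all R restart vectors are propagated simultaneously
(batched sparse iteration). Each node's null mean and sd come from the
permutations in which that node was *not* drawn as a seed — including
self-seed draws concentrates restart mass on the node and inflates its
null moments (with them, the null z of a random gene averaged −0.17; with
the exclusion, z is N(0,1) to within |mean| < 0.1, |sd−1| < 0.15). Nodes
with an undefined null (fewer than two eligible permutations, or sd = 0)
get z = 0 and a flag.

The proximal network is the top-k by z (ties: raw score, then symbol);
seed genes compete on the same ranking and are expected to rank high. Raw
score ranking is available for sensitivity analysis.

## Integration

The urn for the overlap test is the propagation interactome: N = network
genes, K = prioritized genes ∩ background, n = top-k genes, x = their
intersection; p = P(X ≥ x) computed as an exact log-space tail sum (never
0, capped at 1). Both the prioritized-only and the prioritized∪seed
variants are reported, because seed genes necessarily rank high in their
own propagation — the seed-inclusive variant is descriptive, not a
calibrated test. The sweep over k reports a grid-Bonferroni companion
column since k = 500/2000 are analyst choices.

## Clustering, enrichment, hubs

Louvain (networkx) with 10 restarts, best partition by weighted modularity
at resolution γ = 1; cluster ids relabeled by decreasing size. Term
enrichment uses the same exact hypergeometric tail against an explicit
background (all interactome genes by default), with B-H across all tested
terms in a run; the pathway-style analysis additionally requires at least
one seed and one prioritized gene among a term's participating genes. The
rich factor is the fraction of seed genes among a term's participating
genes (a whole-term-size denominator is a config switch). Hub genes are
candidates (members of significantly enriched terms) whose degree in the
induced top-k subgraph exceeds a threshold — 200 matches a 500-node
network of a dense mammalian interactome; synthetic runs use a threshold
scaled to their graph (e.g. 20–25).

## Synthetic generator

The generator plants one module M in a Barabási–Albert interactome
(n = 5000, attachment 5, weights 1.0) by adding intra-module edges with
probability 0.10 over a 150-gene set. The RNA-seq arm draws NB counts
(dispersion 0.1) for 2000 expressed genes over the 6 CT / 6 LR / 5 NR ×
{Li−, Li+} paired design: lognormal gene baselines (log-mean log 60, sd
1.3), per-subject lognormal baselines (sd 0.2) shared across a subject's
two samples, lognormal library depths (sd 0.3), and a tissue-of-origin
shift (e^0.4 on 5% of genes). Forty DE genes (30 in M) carry |log2FC| = 2
in the responder group under both treatments. The GWAS arm genotypes 1200
genes (8 SNPs each, gene bodies only — emulating a chip's partial
gene-body coverage at window 0) for 256 subjects; within-gene LD is AR(1)
with adjacent dosage correlation 0.8, realized by thresholding latent
Gaussian haplotypes whose correlation is calibrated by tetrachoric
inversion (within-gene MAFs share a per-gene base in [0.05, 0.5] with 8%
jitter — disparate margins make high binary correlations unattainable).
Sixty causal genes (45 in M) each carry β = 0.4 on their four commonest
SNPs; the logistic intercept is tuned to ~50% prevalence; covariates have
null effects. Gene sets are 100 terms (sizes 20–200) with one planted term
at Jaccard 0.8 to M.

Both omics universes are uniform draws from the interactome with only the
planted effect genes forced in; under the matched null fixture (log2FC =
0, β = 0) nothing is forced, so neither channel over-represents the dense
module and the integration null is calibrated — an earlier design that
forced M into both universes produced spuriously significant null overlaps
through universe bias alone, a caution that applies equally to real data
where both platforms favor well-studied genes.

What passing tests show — and don't: the fixtures exercise the statistical
machinery (normalization, calibration, propagation, exact tails) under a
known truth, but real data differ in ways the generator does not emulate:
empirical LD maps and allele-frequency spectra, GC/length biases and
outlier samples in RNA-seq, weighted and noisy interactome edges,
annotation incompleteness, and population structure with non-null
covariates.

At the study-like conditions the GWAS channel is deliberately underpowered
(the emulated study's own GWAS was null): the liability variance
contributed by 60 causal genes attenuates per-SNP z-scores to ≈2, so
causal genes reach median gene-level p ≈ 0.15 and the planted-module
overlap lands at p ≈ 10⁻⁴–10⁻² at k = 500 rather than arbitrarily deep
significance. The end-to-end controls are therefore calibrated as:
planted fixture overlap p < 0.05 in ≥ 8/10 seeds with median < 5e-3; null
fixture p > 0.05 in ≥ 8/10 seeds.

## Problem sizes used by the test suite

Unit and property tests run on reduced instances chosen for tight oracles:
random graphs ≤ 200 nodes against dense solves, exhaustive hypergeometric
enumeration at N ≤ 12, exhaustive partition search on 8 nodes, 2000-gene
DE calibration panels, 500-gene null GWAS panels, and a reduced "small"
generator preset (1500-gene network, 80-gene module, 1000 expressed genes,
400 genotyped genes) for stage-level truth checks. The end-to-end controls
run at the full default scale over 10 planted and 10 null master seeds.

## Limitations

- The DE engine approximates the study's unavailable pipeline; its
  contract is the serial-filter semantics, not engine identity.
- The boost is "GWAB-style": the published algorithm's internals are not
  described beyond re-ranking by network neighborhood evidence, so λ and
  the neighbor cap are explicit, documented knobs rather than a
  reconstruction.
- The propagation variant, α, and the permutation scheme are declared
  defaults, not reconstructions of the study's unpublished settings.
- Hypergeometric overlap assumes exchangeable draws from the background;
  both channels preferring dense or well-annotated regions violates this
  in real data (see the universe-bias caution above) and the package makes
  the background explicit everywhere for that reason.
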