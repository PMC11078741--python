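"""Per-SNP association, gene mapping, LD, the empirical gene test and
network boosting."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from netomics import gwas_scoring as gs
from netomics.types import GwasDataset, Interactome, ValidationError


def make_gwas(dosage, y, covs=None, positions=None):
    S, n = dosage.shape
    subjects = [f"S{i}" for i in range(n)]
    snps = pd.DataFrame(
        {"chrom": "1",
         "pos": positions if positions is not None else np.arange(1, S + 1)},
        index=pd.Index([f"snp{i}" for i in range(S)], name="snp"))
    covs = covs if covs is not None else np.zeros((n, 0))
    return GwasDataset(
        snps=snps,
        dosage=pd.DataFrame(dosage, index=snps.index, columns=subjects,
                            dtype=float),
        phenotype=pd.Series(y, index=subjects),
        covariates=pd.DataFrame(covs, index=subjects))


class TestSnpLogistic:
    def test_monomorphic_snp_flagged_and_unscored(self):
        rng = np.random.default_rng(0)
        D = np.vstack([np.ones(60), rng.binomial(2, 0.4, 60)])
        y = rng.binomial(1, 0.5, 60)
        out = gs.snp_logistic_assoc(make_gwas(D, y))
        assert out.loc["snp0", "flag"] == "monomorphic"
        assert np.isnan(out.loc["snp0", "p"])
        assert np.isfinite(out.loc["snp1", "p"])

    def test_matches_statsmodels_logit(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        n = 200
        covs = rng.standard_normal((n, 2))
        D = rng.binomial(2, 0.3, (5, n)).astype(float)
        y = rng.binomial(1, 1 / (1 + np.exp(-(0.3 * D[0] - 0.2))))
        out = gs.snp_logistic_assoc(make_gwas(D, y, covs))
        C = np.column_stack([np.ones(n), covs])
        for i in range(5):
            X = np.column_stack([C, D[i]])
            ref = sm.Logit(y, X).fit(disp=0)
            assert out["beta"].iloc[i] == pytest.approx(ref.params[-1],
                                                        abs=1e-5)
            assert out["se"].iloc[i] == pytest.approx(ref.bse[-1], rel=1e-4)

    def test_planted_effect_recovery(self):
        """Median absolute error of beta-hat over 100 replicate SNPs."""
        rng = np.random.default_rng(2)
        n, reps, beta = 256, 100, 0.5
        D = rng.binomial(2, 0.3, (reps, n)).astype(float)
        errors = []
        # each SNP gets its own phenotype so replicates are independent
        for i in range(reps):
            y = rng.binomial(1, 1 / (1 + np.exp(-(beta * (D[i] - D[i].mean())))))
            out = gs.snp_logistic_assoc(make_gwas(D[i][None, :], y))
            errors.append(abs(out["beta"].iloc[0] - beta))
        assert np.median(errors) < 0.15

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(3)
        n = 256
        D = rng.binomial(2, 0.3, (1000, n)).astype(float)
        y = rng.binomial(1, 0.5, n)
        out = gs.snp_logistic_assoc(make_gwas(D, y))
        ks = stats.kstest(out["p"].dropna(), "uniform").statistic
        assert ks < 0.05

    def test_missing_dosage_mean_imputed(self):
        rng = np.random.default_rng(4)
        D = rng.binomial(2, 0.4, (2, 100)).astype(float)
        D[0, :5] = np.nan
        y = rng.binomial(1, 0.5, 100)
        out = gs.snp_logistic_assoc(make_gwas(D, y))
        assert np.isfinite(out["p"]).all()


class TestSnpGeneMapping:
    @staticmethod
    def models():
        return pd.DataFrame(
            {"chrom": ["1", "1"], "start": [100, 500], "end": [200, 700]},
            index=pd.Index(["gA", "gB"], name="gene"))

    def test_half_open_boundaries(self):
        # 1-based pos 101 -> coord 100 = gA start (inclusive);
        # pos 201 -> coord 200 = gA end (exclusive)
        snps = pd.DataFrame({"chrom": "1", "pos": [101, 201]},
                            index=["s1", "s2"])
        out = gs.map_snps_to_genes(snps, self.models())
        assert out == {"gA": ["s1"]}

    def test_window_extends_assignment(self):
        snps = pd.DataFrame({"chrom": "1", "pos": [95]}, index=["s1"])
        assert gs.map_snps_to_genes(snps, self.models()) == {}
        out = gs.map_snps_to_genes(snps, self.models(), window_bp=10)
        assert out == {"gA": ["s1"]}

    def test_unknown_chromosome_unassigned(self):
        snps = pd.DataFrame({"chrom": "X", "pos": [150]}, index=["s1"])
        assert gs.map_snps_to_genes(snps, self.models()) == {}

    def test_matches_brute_force_interval_scan(self):
        rng = np.random.default_rng(5)
        genes = pd.DataFrame(
            {"chrom": rng.choice(["1", "2"], 50),
             "start": rng.integers(0, 10_000, 50)},
            index=pd.Index([f"g{i}" for i in range(50)], name="gene"))
        genes["end"] = genes["start"] + rng.integers(50, 800, 50)
        snps = pd.DataFrame(
            {"chrom": rng.choice(["1", "2"], 500),
             "pos": rng.integers(1, 11_000, 500)},
            index=pd.Index([f"s{i}" for i in range(500)], name="snp"))
        out = gs.map_snps_to_genes(snps, genes, window_bp=20)
        brute: dict[str, list[str]] = {}
        for s, srow in snps.iterrows():
            for g, grow in genes.iterrows():
                if (srow["chrom"] == grow["chrom"]
                        and grow["start"] - 20 <= srow["pos"] - 1
                        < grow["end"] + 20):
                    brute.setdefault(g, []).append(s)
        assert out == brute


class TestLd:
    def test_duplicated_snp_gives_unit_offdiagonal(self):
        rng = np.random.default_rng(6)
        d = rng.binomial(2, 0.4, 80).astype(float)
        data = make_gwas(np.vstack([d, d]), rng.binomial(1, 0.5, 80))
        ld = gs.ld_from_genotypes(data, {"g": ["snp0", "snp1"]})["g"]
        assert ld[0, 1] == pytest.approx(1.0, abs=1e-9)
        assert np.linalg.eigvalsh(ld).min() >= -1e-10

    def test_independent_snps_near_identity(self):
        rng = np.random.default_rng(7)
        n = 800
        D = rng.binomial(2, 0.4, (6, n)).astype(float)
        data = make_gwas(D, rng.binomial(1, 0.5, n))
        ld = gs.ld_from_genotypes(data, {"g": list(data.snps.index)})["g"]
        off = np.abs(ld[np.triu_indices(6, 1)])
        assert off.mean() < 3 / np.sqrt(n)

    def test_psd_repair_restores_unit_diagonal(self):
        bad = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        fixed = gs.repair_psd(bad)
        assert np.allclose(np.diag(fixed), 1.0)
        assert np.linalg.eigvalsh(fixed).min() >= -1e-12


class TestGeneEmpiricalTest:
    def test_single_snp_recovers_its_p(self):
        p, _, S = gs.gene_empirical_test([0.05], np.eye(1), sims=(20_000,),
                                         rng=np.random.default_rng(0))
        assert abs(p - 0.05) < 3 * np.sqrt(0.05 * 0.95 / S)

    def test_independent_snps_match_chisquare_tail(self):
        rng = np.random.default_rng(1)
        for m in (2, 5, 10):
            p_snp = rng.uniform(0.01, 0.9, m)
            t_obs = np.sum(stats.norm.isf(p_snp / 2) ** 2)
            p, _, S = gs.gene_empirical_test(p_snp, np.eye(m), sims=(20_000,),
                                             rng=rng)
            ref = stats.chi2.sf(t_obs, m)
            assert abs(p - ref) < 3 * np.sqrt(ref * (1 - ref) / S) + 1e-4

    def test_perfectly_correlated_pair_degenerates_to_one_snp(self):
        p1, *_ = gs.gene_empirical_test([0.05], np.eye(1), sims=(50_000,),
                                        rng=np.random.default_rng(2))
        p2, *_ = gs.gene_empirical_test([0.05, 0.05], np.ones((2, 2)),
                                        sims=(50_000,),
                                        rng=np.random.default_rng(2))
        assert abs(p1 - p2) < 0.01

    def test_empirical_p_bounds(self):
        # extreme observed statistic: p hits the +1 floor, never 0
        p, _, S = gs.gene_empirical_test([1e-30], np.eye(1), sims=(1000, 2000),
                                         rng=np.random.default_rng(3))
        assert p == pytest.approx(1 / (1 + S))
        p_hi, *_ = gs.gene_empirical_test([1.0], np.eye(1), sims=(1000,),
                                          rng=np.random.default_rng(4))
        assert p_hi <= 1.0

    def test_adaptive_schedule_escalates_only_for_small_p(self):
        _, _, used_small = gs.gene_empirical_test(
            [0.9], np.eye(1), sims=(1000, 10_000),
            rng=np.random.default_rng(5))
        _, _, used_big = gs.gene_empirical_test(
            [1e-6], np.eye(1), sims=(1000, 10_000),
            rng=np.random.default_rng(5))
        assert used_small == 1000 and used_big == 10_000

    def test_invalid_snp_p_rejected(self):
        with pytest.raises(ValidationError):
            gs.gene_empirical_test([0.0], np.eye(1))


class TestBoostAndSelection:
    def test_edgeless_network_is_identity(self):
        inter = Interactome.from_edges([])
        inter.graph.add_nodes_from(["A", "B"])
        s = pd.Series({"A": 2.0, "B": 1.0})
        out = gs.gwab_boost(s, inter)
        assert out["A"] == 2.0 and out["B"] == 1.0

    def test_star_graph_hand_computation(self):
        inter = Interactome.from_edges(
            [("hub", f"leaf{i}", 1.0) for i in range(4)])
        s = pd.Series({f"leaf{i}": 3.0 for i in range(4)} | {"hub": 0.0,
                                                             "lone": 2.0})
        out = gs.gwab_boost(s, inter, lam=1.0)
        assert out["hub"] == pytest.approx(3.0)    # 0 + mean(3,3,3,3)
        assert out["leaf0"] == pytest.approx(3.0)  # 3 + hub's 0
        assert out["lone"] == pytest.approx(2.0)   # isolated keeps its score
        assert out["hub"] > out["lone"]

    def test_matches_brute_force_recomputation(self, small_bundle):
        inter = small_bundle.interactome
        rng = np.random.default_rng(8)
        nodes = inter.nodes
        s = pd.Series(rng.exponential(1.0, len(nodes)), index=nodes)
        out = gs.gwab_boost(s, inter, lam=0.7, neighbor_cap=10)
        for node in rng.choice(nodes, 40, replace=False):
            nbrs = sorted(inter.graph[node].items(),
                          key=lambda kv: (-kv[1]["weight"], kv[0]))[:10]
            w = np.array([a["weight"] for _, a in nbrs])
            sv = np.array([s[n] for n, _ in nbrs])
            expect = s[node] + 0.7 * (w @ sv) / w.sum() if len(nbrs) else s[node]
            assert out[node] == pytest.approx(expect)

    def test_neighbor_cap_ties_resolved_by_symbol(self):
        inter = Interactome.from_edges(
            [("x", n, 1.0) for n in ["a", "b", "c"]])
        s = pd.Series({"a": 9.0, "b": 0.0, "c": 0.0, "x": 0.0})
        out = gs.gwab_boost(s, inter, lam=1.0, neighbor_cap=2)
        # equal weights: cap keeps 'a' and 'b' (symbol order)
        assert out["x"] == pytest.approx(4.5)

    def test_top_fraction_ceiling_and_ties(self):
        s = pd.Series(np.zeros(100), index=[f"g{i:03d}" for i in range(100)])
        assert len(gs.select_top_fraction(s, 0.05)) == 5
        s2 = pd.Series(np.zeros(101), index=[f"g{i:03d}" for i in range(101)])
        top = gs.select_top_fraction(s2, 0.05)
        assert len(top) == 6
        assert top == sorted(s2.index)[:6]  # full tie -> symbol order
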