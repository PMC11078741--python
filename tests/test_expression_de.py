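"""Normalization, serial DE filtering and the qPCR validation math."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from netomics import expression_de as de
from netomics.types import ValidationError

from conftest import make_experiment, nb_counts


class TestTmmAndCpm:
    def test_identical_libraries_give_unit_factors(self):
        rng = np.random.default_rng(0)
        col = rng.poisson(50, 200)
        exp = make_experiment(np.column_stack([col, col]), ["CT", "CT"])
        f = de.tmm_factors(exp)
        assert np.allclose(f.tmm, 1.0)

    def test_pure_depth_difference_absorbed_by_library_size(self):
        rng = np.random.default_rng(1)
        col = rng.poisson(50, 500)
        exp = make_experiment(np.column_stack([col, 2 * col]), ["CT", "CT"])
        f = de.tmm_factors(exp)
        assert np.allclose(f.tmm, 1.0, atol=1e-9)
        # CPM is then invariant between the two samples
        cpm = de.compute_cpm(exp, f)
        assert np.allclose(cpm.iloc[:, 0], cpm.iloc[:, 1])

    def test_factor_geometric_mean_is_one(self, small_bundle):
        f = de.tmm_factors(small_bundle.counts)
        assert abs(np.mean(np.log(f.tmm))) < 1e-9

    def test_cpm_definition(self):
        exp = make_experiment(np.array([[10], [999_990]]), ["CT"])
        f = de.NormalizationFactors(
            library_size=pd.Series([1e6], index=exp.samples),
            tmm=pd.Series([1.0], index=exp.samples))
        cpm = de.compute_cpm(exp, f)
        assert cpm.iloc[0, 0] == pytest.approx(10.0)

    def test_cpm_matches_elementwise_oracle(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(40, (20, 6))
        exp = make_experiment(counts, ["CT"] * 6)
        f = de.tmm_factors(exp)
        cpm = de.compute_cpm(exp, f)
        for g in range(20):
            for s in range(6):
                eff = counts[:, s].sum() * f.tmm.iloc[s]
                assert cpm.iloc[g, s] == pytest.approx(counts[g, s] / eff * 1e6)

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="Rscript unavailable")
    def test_factors_match_edger_reference(self, tmp_path):
        """Independent reference implementation of the same trim rules."""
        rng = np.random.default_rng(4)
        G, S = 300, 6
        base = np.exp(rng.normal(np.log(80), 1.0, G))
        counts = rng.poisson(
            np.tile(base[:, None], (1, S)) * rng.uniform(0.5, 2.0, S))
        up = rng.choice(G, 15, replace=False)
        counts[up, 0] *= 4
        df = pd.DataFrame(counts, index=[f"g{i}" for i in range(G)],
                          columns=[f"s{i}" for i in range(S)])
        df.to_csv(tmp_path / "counts.tsv", sep="\t")
        script = tmp_path / "tmm.R"
        script.write_text(
            'suppressMessages(library(edgeR))\n'
            f'm <- as.matrix(read.delim("{tmp_path}/counts.tsv", row.names=1))\n'
            'f <- calcNormFactors(m, method="TMM")\n'
            f'write.table(data.frame(factor=f), "{tmp_path}/out.tsv", '
            'sep="\\t", quote=FALSE)\n')
        subprocess.run(["Rscript", str(script)], check=True,
                       capture_output=True)
        ref = pd.read_csv(tmp_path / "out.tsv", sep="\t")["factor"].to_numpy()
        mine = de.tmm_factors(make_experiment(counts, ["CT"] * S)).tmm
        assert np.allclose(mine, ref, rtol=0.02)

    def test_reference_invariance_to_sample_relabeling(self):
        rng = np.random.default_rng(9)
        counts = rng.poisson(60, (300, 5))
        exp = make_experiment(counts, ["CT"] * 5)
        f1 = de.tmm_factors(exp).tmm.to_numpy()
        perm = [3, 1, 4, 0, 2]
        exp2 = make_experiment(counts[:, perm], ["CT"] * 5)
        f2 = de.tmm_factors(exp2).tmm.to_numpy()
        assert np.allclose(f1[perm], f2, atol=1e-9)


class TestLowExpressionFilter:
    def test_boundary_is_strict(self):
        cpm = pd.DataFrame({"s1": [1.0, 5.0], "s2": [1.0, 5.0]},
                           index=["flat", "high"])
        kept = de.filter_low_expression(cpm, threshold=1.0, min_samples=2)
        assert kept == ["high"]

    def test_matches_counting_oracle(self):
        rng = np.random.default_rng(3)
        cpm = pd.DataFrame(rng.exponential(2, (50, 8)),
                           index=[f"g{i}" for i in range(50)])
        kept = set(de.filter_low_expression(cpm, 1.0, min_samples=3))
        oracle = {g for g in cpm.index if (cpm.loc[g] > 1.0).sum() >= 3}
        assert kept == oracle


class TestBhAdjust:
    def test_hand_step_up_example(self):
        q = de.bh_adjust([0.01, 0.02, 0.03])
        assert np.allclose(q, [0.03, 0.03, 0.03])

    def test_degenerate_inputs(self):
        assert de.bh_adjust([0.2])[0] == pytest.approx(0.2)
        assert np.allclose(de.bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_nan_propagates_without_affecting_ranking(self):
        q = de.bh_adjust([0.01, np.nan, 0.02])
        assert np.isnan(q[1])
        assert np.allclose(q[[0, 2]], de.bh_adjust([0.01, 0.02]))

    def test_matches_brute_force_step_up_on_random_vectors(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 40))
            m = len(p)
            order = np.argsort(p)
            brute = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, p[i] * m / rank)
                brute[i] = running
            assert np.allclose(de.bh_adjust(p), brute)

    def test_order_invariance(self):
        rng = np.random.default_rng(12)
        p = rng.uniform(size=25)
        q = de.bh_adjust(p)
        perm = rng.permutation(25)
        assert np.allclose(q[perm], de.bh_adjust(p[perm]))


class TestFitAndSerialFilter:
    def test_gene_failing_lfc_gate_is_not_de(self):
        table = pd.DataFrame(
            {"mean_cpm_a": [10.0], "mean_cpm_b": [5.0], "log2fc": [0.9],
             "p": [0.04], "converged": [True]},
            index=pd.Index(["g1"], name="gene"))
        res = de.serial_filter(de.DEResult("c", table))
        assert res.de_genes == []
        assert bool(res.table.loc["g1", "pass_p"])
        assert not bool(res.table.loc["g1", "pass_lfc"])

    def test_filter_flags_are_monotone_and_tightening_never_adds(self):
        rng = np.random.default_rng(21)
        table = pd.DataFrame(
            {"mean_cpm_a": 10.0, "mean_cpm_b": 10.0,
             "log2fc": rng.normal(0, 1.5, 300),
             "p": rng.uniform(size=300), "converged": True},
            index=pd.Index([f"g{i}" for i in range(300)], name="gene"))
        base = de.serial_filter(de.DEResult("c", table))
        t = base.table
        assert (t["pass_lfc"] <= t["pass_p"]).all()
        assert (t["pass_q"] <= t["pass_lfc"]).all()
        tighter = de.serial_filter(de.DEResult("c", table), p_max=0.01,
                                   lfc_min=1.5, q_max=0.1)
        assert set(tighter.de_genes) <= set(base.de_genes)

    def test_all_zero_arm_yields_finite_log2fc_with_correct_sign(self):
        rng = np.random.default_rng(22)
        counts = nb_counts(rng, np.full(30, 80.0), 0.1, 12)
        counts[0, 6:] = 0  # absent in the second arm
        exp = make_experiment(counts, ["LR"] * 6 + ["NR"] * 6)
        fit = de.fit_de_model(exp, list(exp.genes),
                              de.Contrast.parse("LR_vs_NR@Li-"))
        lfc = fit.table["log2fc"].iloc[0]
        assert np.isfinite(lfc) and lfc > 0  # LR (a) over NR (b)

    def test_matches_statsmodels_nb_glm_coefficients(self):
        """Dual route: batched IRLS vs statsmodels GLM at fixed dispersion."""
        import statsmodels.api as sm

        from netomics import glm

        rng = np.random.default_rng(23)
        Y = nb_counts(rng, np.full(5, 60.0), 0.1, 12).astype(float)
        X = np.column_stack([np.ones(12), [0] * 6 + [1] * 6])
        offset = np.log(np.full(12, 1e4))
        beta, _, _ = glm.nb_irls(Y, X, offset, alpha=0.1, ridge=0.0)
        for i in range(5):
            ref = sm.GLM(Y[i], X, family=sm.families.NegativeBinomial(alpha=0.1),
                         offset=offset).fit()
            assert np.allclose(beta[i], ref.params, atol=1e-5)

    def test_planted_truth_recall_and_fdr(self, small_params):
        """Recall under the serial filters; FDR under genome-wide B-H."""
        from netomics import synthetic_data as sd

        recalls, fdps = [], []
        for seed in range(200, 205):
            b = sd.simulate_bundle(seed=seed, params=small_params)
            exp = b.counts
            truth = set(b.truth.de_genes)
            factors = de.tmm_factors(exp)
            cpm = de.compute_cpm(exp, factors)
            retained = de.filter_low_expression(cpm, exp=exp)
            fit = de.fit_de_model(exp, retained,
                                  de.Contrast.parse("LR_vs_NR@Li-"),
                                  factors=factors)
            serial = de.serial_filter(fit)
            recalls.append(len(set(serial.de_genes) & truth) / len(truth))
            gw = de.serial_filter(fit, qvalue_scope="genome_wide")
            calls = set(gw.de_genes)
            fdps.append(len(calls - truth) / max(len(calls), 1))
        assert np.mean(recalls) >= 0.8
        assert np.mean(fdps) <= 0.25


class TestCompareDeLists:
    def test_two_list_regions(self):
        out = de.compare_de_lists({"x": ["A", "B", "C"], "y": ["B", "C", "D"]})
        out = out.set_index("region")
        assert out.loc["x&y", "exclusive_count"] == 2
        assert out.loc["union", "exclusive_count"] == 4
        assert out.loc["x", "exclusive_count"] == 1

    def test_identical_lists_share_everything(self):
        out = de.compare_de_lists({"x": ["A", "B"], "y": ["A", "B"]})
        out = out.set_index("region")
        assert out.loc["x&y", "exclusive_count"] == 2
        assert out.loc["x", "exclusive_count"] == 0
        assert out.loc["x&y", "pct_of_union"] == 100.0


class TestQpcrUtilities:
    def test_ddct_identity_and_doubling(self):
        fc, _ = de.ddct_fold_change([20, 20, 20], [15, 15, 15],
                                    [22, 22, 22], [17, 17, 17])
        assert fc == pytest.approx(1.0)
        fc2, _ = de.ddct_fold_change([20, 20, 20], [16, 16, 16],
                                     [22, 22, 22], [17, 17, 17])
        assert fc2 == pytest.approx(2.0)  # ddCt = -1

    def test_ddct_sem_matches_propagation_oracle(self):
        ct_t_c = np.array([20.1, 20.4, 19.9])
        ct_r_c = np.array([15.0, 15.2, 14.9])
        ct_t_b = np.array([22.0, 21.8, 22.3])
        ct_r_b = np.array([17.1, 16.9, 17.2])
        fc, sem = de.ddct_fold_change(ct_t_c, ct_r_c, ct_t_b, ct_r_b)
        d_c = ct_t_c - ct_r_c
        d_b = ct_t_b - ct_r_b
        ddct = d_c.mean() - d_b.mean()
        sd = np.sqrt(d_c.var(ddof=1) / 3 + d_b.var(ddof=1) / 3)
        assert fc == pytest.approx(2.0 ** -ddct)
        assert sem == pytest.approx(2.0 ** -ddct * np.log(2) * sd)

    def test_missing_reference_is_fatal(self):
        with pytest.raises(ValidationError, match="reference"):
            de.ddct_fold_change([20], [], [21], [17])

    def test_concordance_perfect_and_sign_blind(self):
        x = np.array([1.0, -2.0, 0.5, 3.0])
        assert de.log2fc_concordance(x, x)[0] == pytest.approx(1.0)
        assert de.log2fc_concordance(x, -x)[0] == pytest.approx(1.0)

    def test_concordance_matches_textbook_formula(self):
        x = np.array([1.0, 2.0, 3.0, 5.0])
        y = np.array([0.8, 2.5, 2.7, 5.5])
        r2, p = de.log2fc_concordance(x, y)
        r = np.corrcoef(x, y)[0, 1]
        t = r * np.sqrt(2 / (1 - r**2))
        assert r2 == pytest.approx(r**2, abs=1e-12)
        assert p == pytest.approx(2 * stats.t.sf(abs(t), 2), abs=1e-12)

    def test_zero_variance_flagged(self):
        with pytest.raises(ValidationError, match="variance"):
            de.log2fc_concordance([1, 1, 1], [1, 2, 3])
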