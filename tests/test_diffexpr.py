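"""Differential-expression statistics: PC adjustment, moderated t, BH, Venn."""

import math
import shutil
import subprocess
import tempfile
import textwrap
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from translatome import diffexpr, simulate
from translatome.diffexpr import (
    VariancePrior,
    bh_adjust,
    call_significant,
    fit_variance_prior,
    moderated_t_test,
    pc_adjust,
    venn_partition,
)


def brute_force_moderated_t(x_stress, x_control, d0, s0_sq):
    """Independent plain-loop evaluation of the moderated-t formulas."""
    results = []
    n1, n2 = len(x_stress[0]), len(x_control[0])
    d_g = n1 + n2 - 2
    for row_s, row_c in zip(x_stress, x_control):
        mean_s = sum(row_s) / n1
        mean_c = sum(row_c) / n2
        lfc = mean_s - mean_c
        ss = sum((v - mean_s) ** 2 for v in row_s) + sum((v - mean_c) ** 2 for v in row_c)
        s2 = ss / d_g
        if math.isinf(d0):
            s2_post, df = s0_sq, math.inf
        elif d0 == 0:
            s2_post, df = s2, d_g
        else:
            s2_post = (d0 * s0_sq + d_g * s2) / (d0 + d_g)
            df = d0 + d_g
        t = lfc / math.sqrt(s2_post * (1 / n1 + 1 / n2))
        if math.isinf(df):
            p = 2 * stats.norm.sf(abs(t))
        else:
            p = 2 * stats.t.sf(abs(t), df)
        results.append((lfc, t, p))
    return results


class TestPcAdjust:
    def test_identity_factor(self, tiny_matrix):
        out = pc_adjust(tiny_matrix, [1.0, 1.0])
        pd.testing.assert_frame_equal(out.values, tiny_matrix.values)

    def test_log2_shift(self, tiny_matrix):
        m = tiny_matrix
        out = pc_adjust(m, [0.5, 0.558])
        s1, s2 = m.sample_ids("stress", "PB")
        assert np.allclose(out.values[s1], m.values[s1] - 1.0)
        # 10.0 with factor 0.558 shifts to 10 + log2(0.558) = 9.1583
        assert 10.0 + math.log2(0.558) == pytest.approx(9.1583, abs=1e-4)
        assert np.allclose(out.values[s2], m.values[s2] + math.log2(0.558))
        # untouched populations
        for sid in m.sample_ids("control", "PB") + m.sample_ids("stress", "TOT"):
            assert np.allclose(out.values[sid], m.values[sid])

    def test_reciprocal_round_trip(self, tiny_matrix):
        out = pc_adjust(pc_adjust(tiny_matrix, [0.558, 0.538]), [1 / 0.558, 1 / 0.538])
        assert np.allclose(
            out.values.to_numpy(), tiny_matrix.values.to_numpy(), atol=1e-12
        )

    def test_factor_count_mismatch(self, tiny_matrix):
        with pytest.raises(ValueError, match="factors"):
            pc_adjust(tiny_matrix, [0.5])


class TestVariancePrior:
    def test_identical_variances_give_complete_shrinkage(self):
        from scipy.special import digamma

        prior = fit_variance_prior(np.full(50, 0.04), 2)
        assert math.isinf(prior.d0)
        # log s^2 is biased low by digamma(d/2) - log(d/2); the fit corrects it
        expected = 0.04 * math.exp(-(digamma(1.0) - math.log(1.0)))
        assert prior.s0_sq == pytest.approx(expected, rel=1e-9)

    def test_hierarchical_parameter_recovery(self):
        # sigma_g^2 ~ s0^2 * d0 / chi2_{d0}, then s_g^2 | sigma^2 ~ sigma^2 chi2_dg / dg
        rng = np.random.default_rng(5)
        d0_true, s0_true, d_g = 4.0, 0.04, 2
        sigma2 = s0_true * d0_true / rng.chisquare(d0_true, size=5000)
        s2 = sigma2 * rng.chisquare(d_g, size=5000) / d_g
        prior = fit_variance_prior(s2, d_g)
        assert prior.d0 == pytest.approx(d0_true, rel=0.25)
        assert prior.s0_sq == pytest.approx(s0_true, rel=0.10)

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError, match="10"):
            fit_variance_prior([0.1, 0.2, 0.3], 2)


class TestModeratedT:
    @pytest.mark.parametrize("d0,s0", [(0.0, 1.0), (4.0, 0.05), (math.inf, 0.03)])
    def test_matches_bruteforce_oracle(self, tiny_matrix, d0, s0):
        xs = tiny_matrix.submatrix("stress", "TOT").to_numpy().tolist()
        xc = tiny_matrix.submatrix("control", "TOT").to_numpy().tolist()
        res = moderated_t_test(tiny_matrix, "TOT", prior=VariancePrior(d0, s0))
        oracle = brute_force_moderated_t(xs, xc, d0, s0)
        for (lfc, t, p), (_, row) in zip(oracle, res.iterrows()):
            assert row["log2fc"] == pytest.approx(lfc, abs=1e-10)
            assert row["t"] == pytest.approx(t, abs=1e-10)
            assert row["p"] == pytest.approx(p, abs=1e-10)

    def test_fitted_prior_matches_bruteforce_oracle(self):
        config = simulate.SimulationConfig(n_genes=40, seed=17)
        _, truth = simulate.simulate_gene_universe(config)
        matrix = simulate.simulate_expression(truth, config).matrix
        res = moderated_t_test(matrix, "TOT")
        prior = res.attrs["prior"]
        xs = matrix.submatrix("stress", "TOT").to_numpy().tolist()
        xc = matrix.submatrix("control", "TOT").to_numpy().tolist()
        oracle = brute_force_moderated_t(xs, xc, prior.d0, prior.s0_sq)
        for (lfc, t, p), (_, row) in zip(oracle, res.iterrows()):
            assert row["t"] == pytest.approx(t, abs=1e-10)
            assert row["p"] == pytest.approx(p, abs=1e-10)

    def test_no_shrinkage_limit_is_ordinary_t(self, tiny_matrix):
        res = moderated_t_test(tiny_matrix, "TOT", prior=VariancePrior(0.0, 1.0))
        xs = tiny_matrix.submatrix("stress", "TOT").to_numpy()
        xc = tiny_matrix.submatrix("control", "TOT").to_numpy()
        t_ref, p_ref = stats.ttest_ind(xs.T, xc.T, equal_var=True)
        assert np.allclose(res["t"], t_ref, atol=1e-10)
        assert np.allclose(res["p"], p_ref, atol=1e-10)

    def test_full_shrinkage_limit(self, tiny_matrix):
        s0 = 0.02
        res = moderated_t_test(tiny_matrix, "TOT", prior=VariancePrior(math.inf, s0))
        lfc = res["log2fc"].to_numpy()
        assert np.allclose(res["t"], lfc / math.sqrt(s0 * (0.5 + 0.5)), atol=1e-12)
        assert np.allclose(res["p"], 2 * stats.norm.sf(np.abs(res["t"])), atol=1e-12)

    def test_null_pvalues_uniform(self):
        """No planted effects: ~5% of moderated-t p-values fall below 0.05."""
        config = simulate.SimulationConfig(
            n_genes=2000, seed=11, transcriptional_effect_sd=0.0,
            class_multipliers=(1.0, 1.0),
        )
        _, truth = simulate.simulate_gene_universe(config)
        experiment = simulate.simulate_expression(truth, config)
        adjusted = pc_adjust(experiment.matrix, list(experiment.factors))
        res = moderated_t_test(adjusted, "TOT")
        assert (res["p"] < 0.05).mean() == pytest.approx(0.05, abs=0.015)

    def test_matches_limma_reference(self):
        """Cross-check prior fit and t-statistics against the Bioconductor fit."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript unavailable")
        config = simulate.SimulationConfig(n_genes=60, seed=3, n_replicates=3)
        _, truth = simulate.simulate_gene_universe(config)
        matrix = simulate.simulate_expression(truth, config).matrix
        res = moderated_t_test(matrix, "TOT")
        sub = matrix.submatrix("stress", "TOT").join(matrix.submatrix("control", "TOT"))
        with tempfile.TemporaryDirectory() as d:
            sub.to_csv(f"{d}/x.tsv", sep="\t")
            script = textwrap.dedent(
                f"""
                suppressMessages(library(limma))
                x <- as.matrix(read.delim("{d}/x.tsv", row.names=1))
                group <- factor(c(rep("stress",3), rep("control",3)),
                                levels=c("control","stress"))
                fit <- eBayes(lmFit(x, model.matrix(~group)))
                out <- data.frame(t=fit$t[,2], d0=fit$df.prior, s02=fit$s2.prior)
                write.csv(out, "{d}/out.csv")
                """
            )
            proc = subprocess.run(
                ["Rscript", "-e", script], capture_output=True, text=True
            )
            assert proc.returncode == 0, proc.stderr
            ref = pd.read_csv(f"{d}/out.csv", index_col=0)
        prior = res.attrs["prior"]
        assert prior.d0 == pytest.approx(ref["d0"].iloc[0], rel=1e-6)
        assert prior.s0_sq == pytest.approx(ref["s02"].iloc[0], rel=1e-6)
        assert np.allclose(res["t"].to_numpy(), ref["t"].to_numpy(), atol=1e-8)

    def test_single_replicate_rejected(self, tiny_matrix):
        m = tiny_matrix
        keep = [s for s in m.values.columns if s != "TOT_stress_2"]
        matrix = diffexpr.ExpressionMatrix(
            values=m.values[keep],
            samples=m.samples[m.samples["sample_id"].isin(keep)].reset_index(drop=True),
        )
        with pytest.raises(ValueError, match="replicates"):
            moderated_t_test(matrix, "TOT")


class TestBH:
    def test_hand_stepup(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_all_equal_and_single(self):
        assert np.allclose(bh_adjust([0.2, 0.2, 0.2]), 0.2)
        assert bh_adjust([0.7])[0] == pytest.approx(0.7)

    @given(st.permutations(list(range(6))))
    def test_order_invariance(self, perm):
        p = np.array([0.001, 0.02, 0.2, 0.5, 0.04, 0.9])
        adj = bh_adjust(p)
        adj_perm = bh_adjust(p[perm])
        assert np.allclose(adj_perm, adj[perm])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestCalls:
    @pytest.mark.parametrize(
        "lfc,fdr,sig,direction",
        [
            (1.0, 0.049, True, "up"),
            (0.99, 0.001, False, "none"),
            (-1.2, 0.05, False, "none"),  # strict FDR inequality
            (-1.2, 0.049, True, "down"),
        ],
    )
    def test_threshold_semantics(self, lfc, fdr, sig, direction):
        frame = pd.DataFrame({"log2fc": [lfc], "fdr": [fdr]}, index=["g"])
        out = call_significant(frame)
        assert bool(out["significant"].iloc[0]) is sig
        assert out["direction"].iloc[0] == direction


class TestVenn:
    def test_printed_upregulated_counts(self):
        tot = {f"t{i}" for i in range(977)}
        pb = set(list(tot)[:457]) | {f"p{i}" for i in range(482 - 457)}
        part = venn_partition(tot, pb)
        assert part.counts == {"both": 457, "only_TOT": 520, "only_PB": 25}

    def test_printed_downregulated_counts(self):
        tot = {f"t{i}" for i in range(1453)}
        pb = set(tot) | {f"p{i}" for i in range(8555 - 1453)}
        part = venn_partition(tot, pb)
        assert part.counts["only_PB"] == 7102

    def test_disjoint_sets(self):
        part = venn_partition({"a"}, {"b"})
        assert part.counts == {"both": 0, "only_TOT": 1, "only_PB": 1}


class TestEmpiricalFdr:
    def test_planted_effect_fdr_controlled(self):
        """Calls at 2-fold / FDR<0.05 keep the empirical FDR near the nominal level."""
        n = 2000
        genes = pd.Index([f"G{i:05d}" for i in range(n)], name="gene_id")
        effect = np.zeros(n)
        effect[:100] = 2.0
        effect[100:200] = -2.0
        truth = simulate.GroundTruth(
            table=pd.DataFrame(
                {
                    "class_label": ["II"] * n,
                    "rel_te": [0.564] * n,
                    "log2_total_change": effect,
                },
                index=genes,
            )
        )
        config = simulate.SimulationConfig(n_genes=n, seed=23)
        experiment = simulate.simulate_expression(truth, config)
        adjusted = pc_adjust(experiment.matrix, list(experiment.factors))
        res = moderated_t_test(adjusted, "TOT")
        called = set(res.index[res["significant"]])
        truly_changed = set(genes[:200])
        assert called, "planted 4-fold effects should be detected"
        false_calls = len(called - truly_changed)
        assert false_calls / len(called) <= 0.07
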