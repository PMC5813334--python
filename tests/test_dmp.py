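"""Moderated differential methylation: oracles, limits, and null behavior."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from episig.io_formats import BetaMatrix
from episig import dmp as dmpm
from episig import synthetic_data as synth
from episig.qc_preprocess import beta_to_m


def _two_group_design(n1, n0):
    return pd.DataFrame(
        {"intercept": 1.0, "group": [1.0] * n1 + [0.0] * n0},
        index=[f"s{j}" for j in range(n1 + n0)],
    )


class TestProbeFits:
    def test_two_group_coef_is_difference_of_means(self):
        rng = np.random.default_rng(0)
        M = pd.DataFrame(rng.normal(size=(5, 12)), columns=[f"s{j}" for j in range(12)])
        design = _two_group_design(5, 7)
        fit = dmpm.fit_probe_models(M, design)
        expected = M.iloc[:, :5].mean(axis=1) - M.iloc[:, 5:].mean(axis=1)
        np.testing.assert_allclose(fit.coef_m, expected, atol=1e-12)

    def test_constant_probe_has_zero_residual_sd(self):
        M = pd.DataFrame(
            np.vstack([np.full(10, 1.5), np.random.default_rng(1).normal(size=10)]),
            columns=[f"s{j}" for j in range(10)],
        )
        fit = dmpm.fit_probe_models(M, _two_group_design(5, 5))
        assert fit.s_g[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(42)
        M = pd.DataFrame(rng.normal(size=(10, 20)), columns=[f"s{j}" for j in range(20)])
        design = _two_group_design(8, 12)
        design["frac_a"] = rng.uniform(0.1, 0.6, 20)
        fit = dmpm.fit_probe_models(M, design)
        X = design.to_numpy()
        for i in range(10):
            # independent oracle: solve the normal equations directly
            coefs = np.linalg.solve(X.T @ X, X.T @ M.iloc[i].to_numpy())
            assert fit.coef_m[i] == pytest.approx(coefs[1], abs=1e-10)
            resid = M.iloc[i].to_numpy() - X @ coefs
            s2 = resid @ resid / (20 - 3)
            assert fit.s_g[i] ** 2 == pytest.approx(s2, abs=1e-10)

    def test_rank_deficient_design_names_columns(self):
        design = _two_group_design(3, 3)
        design["dup"] = design["group"]
        M = pd.DataFrame(np.zeros((2, 6)), columns=design.index)
        with pytest.raises(ValueError, match="collinear.*frac"):
            dmpm.build_design(
                pd.DataFrame(
                    {
                        "sample_id": design.index,
                        "group": ["patient"] * 3 + ["control"] * 3,
                    }
                ),
                cell_fractions=pd.DataFrame(
                    {"a": design["group"], "b": design["group"], "c": 1.0 - 2 * design["group"]},
                    index=design.index,
                ),
            )


class TestEbayes:
    @pytest.fixture(scope="class")
    def fit(self):
        rng = np.random.default_rng(5)
        M = pd.DataFrame(
            rng.normal(size=(200, 16)), columns=[f"s{j}" for j in range(16)]
        )
        return dmpm.fit_probe_models(M, _two_group_design(8, 8))

    def test_vanishing_prior_recovers_ordinary_t(self, fit):
        prior = dmpm.EbayesParams(d0=1e-9, s0_sq=1.0)
        _, table = dmpm.ebayes_moderate(fit, prior)
        ordinary = fit.coef_m / (fit.s_g * np.sqrt(fit.v_g))
        np.testing.assert_allclose(table["t_mod"], ordinary, rtol=1e-6)

    def test_infinite_prior_pools_all_variances(self, fit):
        prior = dmpm.EbayesParams(d0=np.inf, s0_sq=2.0)
        _, table = dmpm.ebayes_moderate(fit, prior)
        expected = fit.coef_m / np.sqrt(2.0 * fit.v_g)
        np.testing.assert_allclose(table["t_mod"], expected, rtol=1e-12)

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(8)
        M = pd.DataFrame(
            rng.normal(size=(10_000, 20)), columns=[f"s{j}" for j in range(20)]
        )
        fit = dmpm.fit_probe_models(M, _two_group_design(10, 10))
        _, table = dmpm.ebayes_moderate(fit)
        ks = sps.kstest(table["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_moment_estimator_recovers_known_prior(self):
        # draw probe variances from the scaled inverse-chi-square prior
        rng = np.random.default_rng(13)
        d0_true, s0_true, df = 8.0, 0.04, 20
        s2_true = d0_true * s0_true / rng.chisquare(d0_true, size=20_000)
        s2_obs = s2_true * rng.chisquare(df, size=20_000) / df
        prior = dmpm.estimate_prior(np.sqrt(s2_obs), df)
        assert prior.d0 == pytest.approx(d0_true, rel=0.1)
        assert prior.s0_sq == pytest.approx(s0_true, rel=0.05)

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
    def test_agrees_with_bioconductor_limma(self, tmp_path):
        rng = np.random.default_rng(21)
        n_probes, n1, n0 = 80, 8, 12
        scale = rng.uniform(0.5, 2.0, size=n_probes)
        M = pd.DataFrame(
            rng.normal(size=(n_probes, n1 + n0)) * scale[:, None],
            index=[f"cg{i}" for i in range(n_probes)],
            columns=[f"s{j}" for j in range(n1 + n0)],
        )
        design = _two_group_design(n1, n0)
        design["frac_a"] = rng.uniform(0.1, 0.5, n1 + n0)
        M.to_csv(tmp_path / "M.tsv", sep="\t")
        design.to_csv(tmp_path / "design.tsv", sep="\t")
        rscript = tmp_path / "oracle.R"
        rscript.write_text(
            """
            suppressMessages(library(limma))
            args <- commandArgs(trailingOnly = TRUE)
            M <- as.matrix(read.delim(args[1], row.names = 1))
            design <- as.matrix(read.delim(args[2], row.names = 1))
            fit <- eBayes(lmFit(M, design))
            out <- data.frame(t = fit$t[, "group"], p = fit$p.value[, "group"],
                              d0 = fit$df.prior, s0sq = fit$s2.prior)
            write.table(out, args[3], sep = "\t", quote = FALSE, row.names = FALSE)
            """
        )
        subprocess.run(
            ["Rscript", str(rscript), str(tmp_path / "M.tsv"),
             str(tmp_path / "design.tsv"), str(tmp_path / "out.tsv")],
            check=True, capture_output=True,
        )
        oracle = pd.read_csv(tmp_path / "out.tsv", sep="\t")
        fit = dmpm.fit_probe_models(M, design)
        prior, table = dmpm.ebayes_moderate(fit)
        assert prior.d0 == pytest.approx(oracle["d0"].iloc[0], rel=1e-4)
        assert prior.s0_sq == pytest.approx(oracle["s0sq"].iloc[0], rel=1e-4)
        np.testing.assert_allclose(table["t_mod"], oracle["t"], rtol=1e-4)
        np.testing.assert_allclose(table["p"], oracle["p"], rtol=1e-4)


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert dmpm.bh_adjust([0.03]) == pytest.approx([0.03])

    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            dmpm.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    @staticmethod
    def _oracle(p):
        # literal step-up: p_adj(i) = min over j >= i of n p_(j) / j, capped at 1
        p = np.asarray(p)
        order = np.argsort(p, kind="stable")
        n = len(p)
        adj = np.empty(n)
        running = 1.0
        for rank in range(n, 0, -1):
            running = min(running, n * p[order[rank - 1]] / rank)
            adj[order[rank - 1]] = running
        return adj

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40)
    )
    @settings(max_examples=100, derandomize=True)
    def test_matches_brute_force_oracle(self, p):
        np.testing.assert_allclose(dmpm.bh_adjust(p), self._oracle(p), atol=1e-12)

    def test_monotone_in_p_ranks(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=100)
        adj = dmpm.bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestCallDmps:
    @pytest.fixture(scope="class")
    def called(self, signature_cohort):
        _, _, beta, sheet, truth = signature_cohort
        design = dmpm.build_design(sheet, truth.cell_fractions)
        M = pd.DataFrame(
            beta_to_m(beta.values.to_numpy()),
            index=beta.probe_ids, columns=beta.sample_ids,
        )
        fit = dmpm.fit_probe_models(M, design)
        _, table = dmpm.ebayes_moderate(fit)
        return dmpm.call_dmps(table, beta, sheet), truth

    def test_dual_threshold(self):
        # one probe fails the effect gate, one the p gate, one passes both
        table = pd.DataFrame(
            {"coef_m": [1.0, 1.0, 1.0], "s_g": 0.1, "df_g": 10, "t_mod": [9.0, 1.0, 9.0],
             "p": [0.00001, 0.02, 0.00001]},
            index=["effect_too_small", "p_too_large", "real"],
        )
        vals = pd.DataFrame(
            {"p1": [0.42, 0.20, 0.20], "p2": [0.44, 0.20, 0.20],
             "c1": [0.50, 0.48, 0.50], "c2": [0.52, 0.52, 0.52]},
            index=table.index,
        )
        sheet = pd.DataFrame(
            {"sample_id": ["p1", "p2", "c1", "c2"], "labeled_sex": "M",
             "group": ["patient", "patient", "control", "control"],
             "age": 1, "role": "training"}
        )
        out = dmpm.call_dmps(table, BetaMatrix(vals), sheet)
        assert out.index.tolist() == ["real"]
        assert out.loc["real", "direction"] == "hypo"

    def test_recovers_planted_signature(self, called):
        dmps, truth = called
        assert set(dmps.index) == set(truth.signature_probes)

    def test_direction_split_matches_planted_signs(self, called):
        dmps, truth = called
        n_hypo = (truth.patient_delta[dmps.index] < 0).sum()
        assert (dmps["direction"] == "hypo").sum() == n_hypo

    def test_invariant_to_sample_and_probe_order(self, signature_cohort):
        _, _, beta, sheet, truth = signature_cohort
        design = dmpm.build_design(sheet, truth.cell_fractions)
        M = pd.DataFrame(
            beta_to_m(beta.values.to_numpy()),
            index=beta.probe_ids, columns=beta.sample_ids,
        )
        rng = np.random.default_rng(0)
        perm_p = rng.permutation(len(beta.probe_ids))
        perm_s = rng.permutation(len(beta.sample_ids))
        beta2 = BetaMatrix(beta.values.iloc[perm_p, perm_s])
        M2 = M.iloc[perm_p, perm_s]
        fit1 = dmpm.fit_probe_models(M, design)
        fit2 = dmpm.fit_probe_models(M2, design)
        _, t1 = dmpm.ebayes_moderate(fit1)
        _, t2 = dmpm.ebayes_moderate(fit2)
        d1 = dmpm.call_dmps(t1, beta, sheet)
        d2 = dmpm.call_dmps(t2, beta2, sheet.sample(frac=1.0, random_state=4))
        assert set(d1.index) == set(d2.index)
        pd.testing.assert_frame_equal(d1, d2.loc[d1.index])

    def test_global_null_yields_almost_no_calls(self):
        cfg = synth.SimulationConfig(n_background_probes=50_000, n_carriers=0, seed=17)
        manifest = synth.generate_manifest(cfg)
        beta, sheet, truth = synth.simulate_cohort(cfg, manifest)
        design = dmpm.build_design(sheet, truth.cell_fractions)
        M = pd.DataFrame(
            beta_to_m(beta.values.to_numpy()),
            index=beta.probe_ids, columns=beta.sample_ids,
        )
        fit = dmpm.fit_probe_models(M, design)
        _, table = dmpm.ebayes_moderate(fit)
        assert len(dmpm.call_dmps(table, beta, sheet)) < 5


class TestClusterPurity:
    def test_simulated_cohort_fully_separates(self, signature_cohort):
        _, _, beta, sheet, truth = signature_cohort
        result = dmpm.signature_cluster_purity(beta, sheet, truth.signature_probes)
        assert result.purity == 1.0

    def test_shuffled_labels_near_majority_fraction(self, signature_cohort):
        _, _, beta, sheet, truth = signature_cohort
        rng = np.random.default_rng(1)
        shuffled = sheet.copy()
        shuffled["group"] = rng.permutation(shuffled["group"].to_numpy())
        result = dmpm.signature_cluster_purity(beta, shuffled, truth.signature_probes)
        # shuffling breaks the label-cluster correspondence: purity falls from
        # 1.0 to roughly the chance agreement of the (unchanged) 7/56 split
        assert 0.5 <= result.purity <= 0.95

    def test_duplicate_noise_free_samples(self):
        vals = pd.DataFrame(
            {"p1": [0.2, 0.3], "p2": [0.2, 0.3], "c1": [0.8, 0.7], "c2": [0.8, 0.7]},
            index=["cgA", "cgB"],
        )
        sheet = pd.DataFrame(
            {"sample_id": list(vals.columns), "labeled_sex": "M",
             "group": ["patient", "patient", "control", "control"],
             "age": 1, "role": "training"}
        )
        result = dmpm.signature_cluster_purity(BetaMatrix(vals), sheet, ["cgA", "cgB"])
        assert result.purity == 1.0

    def test_too_few_probes_rejected(self, signature_cohort):
        _, _, beta, sheet, truth = signature_cohort
        with pytest.raises(ValueError, match="2 signature probes"):
            dmpm.signature_cluster_purity(beta, sheet, truth.signature_probes[:1])
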