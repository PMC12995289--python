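import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

import synerseq as ss
from synerseq.de import CONTRAST_ORDER, design_matrix, fit_nb_glm, wald_contrast


def _toy_cm(mat, n_per_group=2, gene_ids=None):
    design = ss.make_design(n_per_group, (1, 1), seed=0)
    mat = np.asarray(mat)
    gene_ids = gene_ids or [f"g{i}" for i in range(mat.shape[0])]
    counts = pd.DataFrame(mat, index=gene_ids, columns=design["sample_id"].to_numpy())
    return ss.CountMatrix(counts=counts, design=design)


class TestFilterLowCounts:
    def test_boundary_at_min_total(self):
        mat = np.zeros((2, 8), int)
        mat[0, 0] = 9   # row sum 9: removed
        mat[1, :5] = 2  # row sum 10: kept
        cm = ss.filter_low_counts(_toy_cm(mat))
        assert cm.gene_ids == ["g1"]

    def test_zero_threshold_is_identity(self):
        rng = np.random.default_rng(0)
        cm = _toy_cm(rng.poisson(5, (20, 8)))
        out = ss.filter_low_counts(cm, min_total=0)
        pd.testing.assert_frame_equal(out.counts, cm.counts)

    def test_matches_row_sum_oracle(self):
        rng = np.random.default_rng(1)
        mat = rng.poisson(1.5, (100, 8))
        cm = ss.filter_low_counts(_toy_cm(mat))
        expected = [f"g{i}" for i in range(100) if mat[i].sum() >= 10]
        assert cm.gene_ids == expected

    def test_empty_result_warns(self):
        with pytest.warns(UserWarning, match="removed every gene"):
            ss.filter_low_counts(_toy_cm(np.zeros((3, 8), int)))


class TestSizeFactors:
    def test_doubled_column_recovered(self):
        rng = np.random.default_rng(2)
        base = rng.poisson(50, 100) + 1
        mat = np.column_stack([base] * 8)
        mat[:, 1] *= 2
        sf = ss.estimate_size_factors(_toy_cm(mat))
        assert sf[1] / sf[0] == pytest.approx(2.0)

    def test_identical_columns_give_unit_factors(self):
        base = np.random.default_rng(3).poisson(30, 50) + 1
        sf = ss.estimate_size_factors(_toy_cm(np.column_stack([base] * 8)))
        assert sf == pytest.approx(np.ones(8))

    def test_matches_brute_force_oracle(self):
        # odd gene count so the median is an order statistic and the
        # ratio-scale and log-scale medians coincide exactly
        rng = np.random.default_rng(4)
        mat = rng.poisson(40, (61, 8)) + 1
        sf = ss.estimate_size_factors(_toy_cm(mat))
        # independent oracle: literal per-gene ratio to geometric mean, median per sample
        geo = np.exp(np.mean(np.log(mat), axis=1))
        oracle = np.median(mat / geo[:, None], axis=0)
        assert sf == pytest.approx(oracle)

    def test_matches_pydeseq2(self):
        from pydeseq2.preprocessing import deseq2_norm

        rng = np.random.default_rng(5)
        mat = rng.negative_binomial(20, 0.3, (80, 8)) + 1
        sf = ss.estimate_size_factors(_toy_cm(mat))
        _, sf_ref = deseq2_norm(pd.DataFrame(mat.T))
        assert sf == pytest.approx(np.asarray(sf_ref).ravel(), rel=1e-10)

    def test_no_all_positive_gene_errors(self):
        mat = np.array([[0, 1, 2, 3, 0, 1, 2, 3], [5, 0, 5, 5, 5, 5, 5, 5]])
        with pytest.raises(ValueError, match="cannot normalize"):
            ss.estimate_size_factors(_toy_cm(mat))


class TestFitNbGlm:
    def test_flat_means_give_zero_effects(self):
        design = ss.make_design(7, (1, 1), seed=0)
        y = np.full(28, 200.0)
        fit = fit_nb_glm(y, design, np.ones(28))
        assert fit.converged
        assert fit.coef[1:] == pytest.approx(np.zeros(3), abs=1e-6)

    def test_saturated_recovery_of_planted_betas(self):
        # 4 cell means, 4 parameters: noise-free expected counts must return
        # the planted coefficients essentially exactly
        design = ss.make_design(7, (1, 1), seed=0)
        bd, bt, bi = 1.25, -0.75, 0.5
        X = design_matrix(design)
        y = 2 ** (8.0 + X[:, 1] * bd + X[:, 2] * bt + X[:, 3] * bi)
        fit = fit_nb_glm(y, design, np.ones(28))
        assert fit.coef == pytest.approx([8.0, bd, bt, bi], abs=1e-6)

    def test_covariance_symmetric_psd(self):
        design = ss.make_design(7, (0.7, 1.4), seed=1)
        truth = ss.plant_archetypes({"synergistic": 1}, seed=2)
        cm = ss.simulate_counts(truth, design, seed=3)
        fit = fit_nb_glm(cm.counts.to_numpy()[0], design, design["size_factor"].to_numpy())
        assert np.allclose(fit.cov, fit.cov.T)
        assert (np.linalg.eigvalsh(fit.cov) > 0).all()

    def test_mean_estimate_unbiased(self, design7):
        # 500 replicate genes with beta_temp=1: mean estimate within 0.05
        truth = ss.plant_archetypes({"null": 500}, dispersion=0.05, seed=31)
        truth["beta_temp"] = 1.0
        cm = ss.simulate_counts(truth, design7, seed=32)
        sf = design7["size_factor"].to_numpy()
        mat = cm.counts.to_numpy(float)
        est = np.array([fit_nb_glm(mat[i], design7, sf).coef[2] for i in range(500)])
        assert abs(est.mean() - 1.0) < 0.05

    def test_matches_pydeseq2_lfcs(self):
        # independent oracle: DESeq2's unshrunk MLE log2 fold changes on the
        # same counts (both engines use median-of-ratios normalization)
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.default_inference import DefaultInference

        design = ss.make_design(5, (1, 1), seed=0)
        truth = ss.plant_archetypes(3, effect_size=1.2, dispersion=0.05, seed=41)
        cm = ss.simulate_counts(truth, design, seed=42)
        de = ss.run_de(cm, min_total=0)

        meta = design.set_index("sample_id")[["diet", "temperature"]].copy()
        meta["diet"] = pd.Categorical(meta["diet"], categories=["Ctrl", "MetR"])
        meta["temperature"] = pd.Categorical(meta["temperature"], categories=["RT", "CE"])
        dds = DeseqDataSet(
            counts=cm.counts.T,
            metadata=meta,
            design="~diet + temperature + diet:temperature",
            inference=DefaultInference(n_cpus=1),
            quiet=True,
        )
        dds.deseq2()
        lfc = dds.varm["LFC"] / np.log(2)
        cols = dds.obsm["design_matrix"].columns
        # dispersion machinery differs (per-gene CR-adjusted vs shrunk MAP),
        # so MLE fold changes agree closely but not to machine precision
        for contrast, ref_col in zip(["B", "A", "INT"], cols[1:]):
            ours = de[de["contrast"] == contrast].set_index("gene_id")["log2fc"]
            assert np.abs(ours - lfc[ref_col].loc[ours.index]).max() < 0.05


class TestWaldContrast:
    def test_contrast_linearity_identity(self, default_sim):
        _, _, de = default_sim
        w = de.pivot(index="gene_id", columns="contrast", values="log2fc").dropna()
        assert np.abs(w["AB"] - (w["A"] + w["B"] + w["INT"])).max() < 1e-9

    def test_null_fit_gives_zero_fc_unit_p(self):
        fit = ss.GeneFit("g", np.array([5.0, 0, 0, 0]), np.eye(4) * 0.01, 0.1, True)
        for c in CONTRAST_ORDER:
            l2fc, se, w, p = wald_contrast(fit, c)
            assert l2fc == 0 and w == 0 and p == 1.0

    def test_unconverged_fit_gives_missing(self):
        fit = ss.GeneFit("g", np.zeros(4), np.eye(4), 0.1, False)
        assert all(np.isnan(wald_contrast(fit, "A")))


class TestAdjustBH:
    def test_hand_executed_step_up(self):
        assert ss.adjust_bh([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert ss.adjust_bh([0.3]) == pytest.approx([0.3])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ss.adjust_bh([0.5, 1.2])

    def test_nan_excluded_from_m(self):
        out = ss.adjust_bh([0.01, np.nan, 0.04])
        assert np.isnan(out[1])
        assert out[[0, 2]] == pytest.approx(multipletests([0.01, 0.04], method="fdr_bh")[1])

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=60))
    def test_matches_statsmodels_oracle_and_bounds(self, pvals):
        ours = ss.adjust_bh(pvals)
        ref = multipletests(pvals, method="fdr_bh")[1]
        assert ours == pytest.approx(ref)
        assert (ours >= np.asarray(pvals) - 1e-15).all() and (ours <= 1).all()


class TestRunDe:
    def test_null_matrix_few_degs(self, null_sim):
        _, _, de = null_sim
        for c in CONTRAST_ORDER:
            sub = de[de["contrast"] == c]
            frac = ((sub["padj"] < 0.05) & (sub["log2fc"].abs() >= 0.585)).mean()
            assert frac <= 0.01

    def test_planted_single_factor_power(self, design7):
        # A_only genes at e=2: called in A and AB, rarely in B
        truth = ss.plant_archetypes({"A_only": 100, "null": 400}, effect_size=2.0, seed=51)
        cm = ss.simulate_counts(truth, design7, seed=52)
        de = ss.run_de(cm)
        th = ss.Thresholds()
        planted = truth[truth["archetype"] == "A_only"]["gene_id"]
        calls = {}
        for c in ("A", "B", "AB"):
            sub = de[(de["contrast"] == c) & de["gene_id"].isin(planted)]
            called = [
                ss.call_direction(fc, pa, th) != "Unchanged"
                for fc, pa in zip(sub["log2fc"], sub["padj"])
            ]
            calls[c] = np.mean(called)
        assert calls["A"] >= 0.9 and calls["AB"] >= 0.9 and calls["B"] <= 0.05

    def test_deterministic_rerun(self, design7):
        truth = ss.plant_archetypes(5, seed=61)
        cm = ss.simulate_counts(truth, design7, seed=62)
        pd.testing.assert_frame_equal(ss.run_de(cm), ss.run_de(cm))

    def test_padj_monotone_in_pvalue_rank(self, default_sim):
        _, _, de = default_sim
        for c in CONTRAST_ORDER:
            sub = de[de["contrast"] == c].dropna().sort_values("pvalue")
            assert (np.diff(sub["padj"]) >= -1e-12).all()
            assert (sub["padj"] >= sub["pvalue"] - 1e-12).all()
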