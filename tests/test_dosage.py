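"""Dosage-response regression, ΔE metrics, FDR, bootstrap, saturation."""

import numpy as np
import pandas as pd
import pytest

from xidosage import dosage as ds
from xidosage import simulate as sim
from xidosage.io import meta_frame
from xidosage.types import SampleMeta


def normal_equations_oracle(X, y):
    """Brute-force OLS via explicit normal equations."""
    XtX = np.zeros((X.shape[1], X.shape[1]))
    Xty = np.zeros(X.shape[1])
    for i in range(X.shape[0]):
        XtX += np.outer(X[i], X[i])
        Xty += X[i] * y[i]
    beta = np.linalg.solve(XtX, Xty)
    resid = y - X @ beta
    df = X.shape[0] - X.shape[1]
    sigma2 = resid @ resid / df
    cov = sigma2 * np.linalg.inv(XtX)
    return beta, cov


class TestBuildDesign:
    def test_npx_par_uses_all_samples(self, lcl_meta):
        info = ds.build_design(lcl_meta, "NPX_PAR")
        assert info.n == 106
        # intercept column first; xi_count dosage second
        assert info.columns[0] == "intercept"
        assert info.columns[info.dosage_col] == "xi_count"

    def test_npy_subset_is_y_positive(self, lcl_meta):
        info = ds.build_design(lcl_meta, "NPY")
        assert info.n == int((lcl_meta["y_count"] >= 1).sum())
        # intercept represents 46,XY: dosage term is y_count - 1
        assert "y_minus_1" in info.columns

    def test_xist_subset_two_or_more_x(self, lcl_meta):
        info = ds.build_design(lcl_meta, "XIST")
        assert info.n == int((lcl_meta["x_count"] >= 2).sum())

    def test_chr21_subset(self):
        metas = [
            SampleMeta.from_karyotype("a", "46,XX", batch="b1"),
            SampleMeta.from_karyotype("b", "46,XY", batch="b1"),
            SampleMeta.from_karyotype("c", "47,XX,+21", batch="b1"),
            SampleMeta.from_karyotype("d", "47,XY,+21", batch="b1"),
            SampleMeta.from_karyotype("e", "47,XXX", batch="b1"),
        ]
        info = ds.build_design(meta_frame(metas), "CHR21")
        assert info.n == 4  # trisomy/euploid karyotypes only

    def test_single_dosage_level_rejected(self):
        metas = [
            SampleMeta.from_karyotype(f"s{i}", "46,XX", batch="b1")
            for i in range(5)
        ]
        with pytest.raises(ValueError, match="dosage levels"):
            ds.build_design(meta_frame(metas), "NPX_PAR")


class TestFitGene:
    def test_exact_linear_data(self, lcl_meta):
        xi = lcl_meta["xi_count"].to_numpy(float)
        y = 100.0 + 50.0 * xi
        counts = pd.DataFrame([y], index=["g"], columns=lcl_meta.index)
        fits = ds.fit_dosage(counts, lcl_meta, "NPX_PAR")
        assert fits.loc["g", "beta_dose"] == pytest.approx(50.0, abs=1e-9)
        assert fits.loc["g", "beta0_avg"] == pytest.approx(100.0, abs=1e-9)
        assert fits.loc["g", "sigma2"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self, lcl_meta):
        rng = np.random.default_rng(1)
        info = ds.build_design(lcl_meta, "NPX_PAR")
        Y = rng.normal(500, 60, size=(len(lcl_meta), 40))
        beta, sigma2, XtX_inv, df = ds.ols_fit(info.X, Y)
        for g in range(40):
            b_o, cov_o = normal_equations_oracle(info.X, Y[:, g])
            assert np.allclose(beta[:, g], b_o, atol=1e-8)
            assert np.allclose(sigma2[g] * XtX_inv, cov_o, atol=1e-8)

    def test_batch_average_intercept(self):
        """Two equal-size batches offset +10/-10: beta0_avg equals the
        batch-free intercept."""
        metas = []
        for i in range(20):
            karyo = ["45,X", "46,XY", "47,XXX", "47,XXY"][i % 4]
            metas.append(
                SampleMeta.from_karyotype(
                    f"s{i}", karyo, batch="b1" if i < 10 else "b2"
                )
            )
        meta = meta_frame(metas)
        xi = meta["xi_count"].to_numpy(float)
        offset = np.where(meta["batch"] == "b1", 10.0, -10.0)
        y = 200.0 + 30.0 * xi + offset
        counts = pd.DataFrame([y], index=["g"], columns=meta.index)
        fits = ds.fit_dosage(counts, meta, "NPX_PAR")
        assert fits.loc["g", "beta0_avg"] == pytest.approx(200.0, abs=1e-8)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="more rows"):
            ds.ols_fit(np.ones((3, 4)), np.ones((3, 2)))


class TestDeltaE:
    def test_zero_coefficient_gives_zero(self, lcl_meta):
        y = np.full(len(lcl_meta), 300.0)
        counts = pd.DataFrame([y], index=["g"], columns=lcl_meta.index)
        de = ds.dosage_analysis(counts, lcl_meta, "NPX_PAR", "X")
        assert de.loc["g", "value"] == pytest.approx(0.0, abs=1e-12)

    def test_equal_contribution_gives_one(self, lcl_meta):
        """beta_X equal to the baseline means Xa and Xi contribute equally."""
        xi = lcl_meta["xi_count"].to_numpy(float)
        counts = pd.DataFrame(
            [250.0 + 250.0 * xi], index=["g"], columns=lcl_meta.index
        )
        de = ds.dosage_analysis(counts, lcl_meta, "NPX_PAR", "X")
        assert de.loc["g", "value"] == pytest.approx(1.0, abs=1e-10)

    def test_xist_variant_with_zero_intercept(self, lcl_meta):
        """Expression proportional to Xi count: the variant denominator
        (beta0 + betaX) forces ΔE_X = 1."""
        xi = lcl_meta["xi_count"].to_numpy(float)
        counts = pd.DataFrame(
            [400.0 * xi], index=["XIST"], columns=lcl_meta.index
        )
        de = ds.dosage_analysis(counts, lcl_meta, "XIST", "X")
        assert de.loc["XIST", "value"] == pytest.approx(1.0, abs=1e-9)

    def test_nonpositive_baseline_flagged(self, lcl_meta):
        xi = lcl_meta["xi_count"].to_numpy(float)
        counts = pd.DataFrame(
            [-50.0 + 10.0 * xi], index=["g"], columns=lcl_meta.index
        )
        de = ds.dosage_analysis(counts, lcl_meta, "NPX_PAR", "X")
        assert bool(de.loc["g", "flagged"])
        assert np.isnan(de.loc["g", "value"])

    def test_scale_invariance(self, lcl_meta):
        rng = np.random.default_rng(12)
        xi = lcl_meta["xi_count"].to_numpy(float)
        y = 300 + 90 * xi + rng.normal(0, 20, len(xi))
        counts = pd.DataFrame([y, y * 7.5], index=["a", "b"],
                              columns=lcl_meta.index)
        de = ds.dosage_analysis(counts, lcl_meta, "NPX_PAR", "X")
        assert de.loc["a", "value"] == pytest.approx(
            de.loc["b", "value"], abs=1e-8
        )

    def test_recovery_within_three_se(self, lcl_cohort, lcl_meta):
        metas, truths = lcl_cohort
        genes = [sim.GeneTruth("g", 700.0, 0.5, 0.0, dispersion=0.05)]
        counts = sim.generate_counts(genes, metas, truths, seed=5)
        tf = sim.sample_truth_frame(truths)
        norm = counts / (tf["depth_factor"] * tf["batch_effect"])
        de = ds.dosage_analysis(norm, lcl_meta, "NPX_PAR", "X")
        assert abs(de.loc["g", "value"] - 0.5) < 3 * de.loc["g", "se"]


class TestFdrAdjust:
    def brute_force_bh(self, p):
        n = len(p)
        order = np.argsort(p)
        adj = np.empty(n)
        prev = 1.0
        for rank_from_top in range(n, 0, -1):
            i = order[rank_from_top - 1]
            val = min(prev, p[i] * n / rank_from_top)
            adj[i] = val
            prev = val
        return adj

    def test_hand_example(self):
        out = ds.fdr_adjust([0.01, 0.02, 0.03])
        assert np.allclose(out, [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert ds.fdr_adjust([0.37])[0] == pytest.approx(0.37)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0, 1, 100)
        assert np.allclose(ds.fdr_adjust(p), self.brute_force_bh(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ds.fdr_adjust([0.5, 1.5])

    def test_order_preserving(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(0, 1, 50)
        adj = ds.fdr_adjust(p)
        assert np.all(np.diff(adj[np.argsort(p)]) >= -1e-12)


class TestBootstrap:
    def test_noiseless_data_zero_width(self, lcl_meta):
        xi = lcl_meta["xi_count"].to_numpy(float)
        counts = pd.DataFrame(
            [100.0 + 40.0 * xi], index=["g"], columns=lcl_meta.index
        )
        out = ds.bootstrap_delta_e(counts, lcl_meta, n_boot=20, seed=0)
        assert out.loc["g", "ci_hi"] - out.loc["g", "ci_lo"] == pytest.approx(
            0.0, abs=1e-10
        )

    def test_single_resample_interval(self, lcl_meta):
        rng = np.random.default_rng(2)
        xi = lcl_meta["xi_count"].to_numpy(float)
        counts = pd.DataFrame(
            [200 + 50 * xi + rng.normal(0, 10, len(xi))],
            index=["g"], columns=lcl_meta.index,
        )
        out = ds.bootstrap_delta_e(counts, lcl_meta, n_boot=1, seed=3)
        assert out.loc["g", "ci_lo"] == pytest.approx(out.loc["g", "ci_hi"])


class TestSexStratified:
    def test_no_y_effect_strata_match_pooled(self, lcl_cohort, lcl_meta):
        metas, truths = lcl_cohort
        genes = [
            sim.GeneTruth(f"g{i}", 500.0 + 100 * i, 0.1 * i, 0.0,
                          dispersion=0.02)
            for i in range(6)
        ]
        counts = sim.generate_counts(genes, metas, truths, seed=8)
        tf = sim.sample_truth_frame(truths)
        norm = counts / (tf["depth_factor"] * tf["batch_effect"])
        out = ds.sex_stratified_delta_e(norm, lcl_meta)
        assert out["correlation_female"] > 0.95
        assert out["correlation_male"] > 0.95

    def test_y_effect_rescales_male_baseline_only(self, lcl_cohort, lcl_meta):
        """Dropping the Y term folds a Y effect into the stratum baseline:
        females recover f + m while males recover (f + m) / (1 + y_effect)."""
        metas, truths = lcl_cohort
        genes = [sim.GeneTruth("g", 600.0, 0.4, 0.0, y_effect=0.5,
                               dispersion=0.02)]
        counts = sim.generate_counts(genes, metas, truths, seed=9)
        tf = sim.sample_truth_frame(truths)
        norm = counts / (tf["depth_factor"] * tf["batch_effect"])
        out = ds.sex_stratified_delta_e(norm, lcl_meta)
        f_se = out["female"].loc["g", "se"]
        m_se = out["male"].loc["g", "se"]
        assert out["female"].loc["g", "value"] == pytest.approx(0.4, abs=3 * f_se)
        assert out["male"].loc["g", "value"] == pytest.approx(
            0.4 / 1.5, abs=3 * m_se
        )

    def test_degenerate_subset_rejected(self):
        metas = [
            SampleMeta.from_karyotype(f"s{i}", k, batch="b1")
            for i, k in enumerate(["46,XY", "47,XXY", "48,XXXY", "46,XY"])
        ]
        meta = meta_frame(metas)
        counts = pd.DataFrame(
            [[100.0] * 4], index=["g"], columns=meta.index
        )
        with pytest.raises(ValueError):
            ds.sex_stratified_delta_e(counts, meta)


class TestSaturation:
    def test_full_cohort_reproduces_full_analysis(self, lcl_cohort, lcl_meta):
        metas, truths = lcl_cohort
        genes, _ = sim.generate_genes(n_genes=20, seed=3, n_background=0)
        counts = sim.generate_counts(genes, metas, truths, seed=3)
        tf = sim.sample_truth_frame(truths)
        norm = counts / (tf["depth_factor"] * tf["batch_effect"])
        full = ds.dosage_analysis(norm, lcl_meta, "NPX_PAR", "X")
        n_full = int((full["fdr"] < 0.05).sum())
        out = ds.saturation_analysis(norm, lcl_meta, [106], reps=3, seed=0)
        assert (out["n_significant"] == n_full).all()
        assert len(out) == 3

    def test_median_nondecreasing_in_n(self, lcl_cohort, lcl_meta):
        metas, truths = lcl_cohort
        genes, _ = sim.generate_genes(n_genes=30, seed=6, n_background=0)
        counts = sim.generate_counts(genes, metas, truths, seed=6)
        tf = sim.sample_truth_frame(truths)
        norm = counts / (tf["depth_factor"] * tf["batch_effect"])
        out = ds.saturation_analysis(
            norm, lcl_meta, [30, 60, 106], reps=8, seed=1
        )
        med = out.groupby("n")["n_significant"].median()
        # allow small sampling wiggle
        assert med.loc[106] >= med.loc[30] - 1

    def test_oversized_subset_rejected(self, lcl_meta):
        counts = pd.DataFrame(
            [[1.0] * len(lcl_meta)], index=["g"], columns=lcl_meta.index
        )
        with pytest.raises(ValueError, match="exceeds"):
            ds.saturation_analysis(counts, lcl_meta, [500], reps=1, seed=0)
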