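"""DE engine: normalization, dispersion recovery, Wald calibration, BH."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from axoprop import diffexpr, synthetic
from axoprop.diffexpr import (
    adjust_bh,
    compute_size_factors,
    estimate_dispersions,
    fit_contrast,
    length_offsets,
    pca_check,
    run_de,
)


def _toy_counts():
    K = np.array([[10, 20, 40],
                  [5, 10, 15],
                  [100, 150, 300],
                  [8, 32, 20],
                  [50, 100, 160]])
    return pd.DataFrame(K, index=[f"g{i}" for i in range(5)],
                        columns=["s1", "s2", "s3"])


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        np.testing.assert_allclose(compute_size_factors(counts), [1.0, 1.0])

    def test_doubled_sample_doubles_factor(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]})
        s = compute_size_factors(counts)
        assert np.isclose(s["b"] / s["a"], 2.0)

    def test_matches_hand_median_of_ratios(self):
        # frozen hand computation on the 5-gene × 3-sample toy
        s = compute_size_factors(_toy_counts())
        np.testing.assert_allclose(
            s.to_numpy(), [0.53860867, 1.07721735, 1.72354775], atol=1e-8)

    def test_no_usable_gene_raises_with_fallback_hint(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [3, 0]})
        with pytest.raises(ValueError, match="pseudo_reference"):
            compute_size_factors(counts)
        s = compute_size_factors(counts, pseudo_reference=True)
        assert (s > 0).all()

    @given(c=st.integers(min_value=1, max_value=20))
    @settings(max_examples=25, deadline=None)
    def test_scale_equivariance(self, c):
        counts = _toy_counts()
        scaled = counts.copy()
        scaled["s2"] = counts["s2"] * c
        base = compute_size_factors(counts)
        s = compute_size_factors(scaled)
        # factors are defined up to a common rescaling: relative to the
        # untouched samples, the scaled sample's factor grows c-fold and
        # the ratio of untouched samples is preserved
        assert np.isclose((s["s2"] / s["s1"]) / (base["s2"] / base["s1"]),
                          c, rtol=1e-12)
        assert np.isclose(s["s3"] / s["s1"], base["s3"] / base["s1"],
                          rtol=1e-12)


class TestLengthOffsets:
    def _meta(self):
        return synthetic.sample_metadata(2)

    def test_equal_lengths_zero_offsets(self):
        ortho = pd.DataFrame({"length_mouse": [1000.0, 2000.0],
                              "length_jerboa": [1000.0, 2000.0]},
                             index=["g1", "g2"])
        o = length_offsets(ortho, self._meta())
        np.testing.assert_allclose(o.to_numpy(), 0.0)

    def test_double_length_gives_symmetric_log_offsets(self):
        ortho = pd.DataFrame({"length_mouse": [1000.0],
                              "length_jerboa": [2000.0]}, index=["g1"])
        o = length_offsets(ortho, self._meta())
        mouse_cols = [c for c in o.columns if c.startswith("mouse")]
        jerboa_cols = [c for c in o.columns if c.startswith("jerboa")]
        np.testing.assert_allclose(o[jerboa_cols], np.log(np.sqrt(2.0)))
        np.testing.assert_allclose(o[mouse_cols], -np.log(np.sqrt(2.0)))

    def test_missing_length_raises(self):
        ortho = pd.DataFrame({"length_mouse": [1000.0],
                              "length_jerboa": [np.nan]}, index=["g1"])
        with pytest.raises(ValueError, match="missing"):
            length_offsets(ortho, self._meta())

    def test_length_proportional_counts_give_zero_lfc(self):
        # counts scaling exactly with transcript length: offset removes it
        rng = np.random.default_rng(0)
        meta = synthetic.sample_metadata(4)
        ratio = np.array([2.0, 0.5, 3.0])
        ortho = pd.DataFrame(
            {"length_mouse": [1000.0, 1000.0, 1000.0],
             "length_jerboa": 1000.0 * ratio},
            index=["g0", "g1", "g2"])
        geo = np.sqrt(ortho["length_mouse"] * ortho["length_jerboa"])
        base = np.array([500.0, 800.0, 300.0])
        rows = []
        for _, row in meta.iterrows():
            lr = (ortho[f"length_{row['species']}"] / geo).to_numpy()
            rows.append(rng.poisson(base * lr * 20))
        counts = pd.DataFrame(np.array(rows).T, index=ortho.index,
                              columns=meta.index)
        sf = pd.Series(1.0, index=meta.index)
        off = length_offsets(ortho, meta)
        disp = pd.Series(1e-8, index=ortho.index)
        res = fit_contrast(counts, sf, off, disp, "jTV6_vs_mTV6", meta)
        assert np.abs(res["lfc"]).max() < 0.1


class TestDispersions:
    def _sim(self, alpha, n_reps, seed=0, n_genes=300):
        cfg = synthetic.SimConfig(
            n_genes=n_genes, n_reps=n_reps, dispersion=alpha,
            frac_equivalent=0, frac_A=0, frac_B=0, length_log_sd=0.0,
            baseline_log_sd=0.5, seed=seed)
        counts, meta, _ = synthetic.simulate_counts(cfg)
        sf = compute_size_factors(counts)
        return counts, sf, meta

    def test_recovers_alpha_within_10pct(self):
        counts, sf, meta = self._sim(0.1, n_reps=50, seed=5)
        disp = estimate_dispersions(counts, sf, meta)
        assert abs(disp.mean() - 0.1) / 0.1 < 0.10

    def test_poisson_counts_give_near_zero_alpha(self):
        counts, sf, meta = self._sim(0.0, n_reps=20, seed=6)
        disp = estimate_dispersions(counts, sf, meta)
        assert np.median(disp) < 1e-3

    def test_constant_counts_hit_floor(self):
        meta = synthetic.sample_metadata(3)
        counts = pd.DataFrame(
            np.full((4, len(meta)), 50), columns=meta.index,
            index=[f"g{i}" for i in range(4)])
        sf = pd.Series(1.0, index=meta.index)
        disp = estimate_dispersions(counts, sf, meta)
        assert (disp <= 1e-6).all()

    def test_single_replicate_group_rejected(self):
        meta = synthetic.sample_metadata(2).iloc[:-1]
        counts = pd.DataFrame(
            np.ones((3, len(meta)), dtype=int) * 10, columns=meta.index)
        sf = pd.Series(1.0, index=meta.index)
        with pytest.raises(ValueError, match="< 2 replicates"):
            estimate_dispersions(counts, sf, meta)


class TestFitContrast:
    def test_identical_groups_give_zero_lfc_p_one(self):
        meta = synthetic.sample_metadata(3)
        row = [10, 20, 30] * 4 + [0] * 0
        counts = pd.DataFrame(
            {s: [row[i % 3] * 2] for i, s in enumerate(meta.index)})
        counts.index = ["g0"]
        # same per-replicate profile in every group
        values = np.tile([10, 20, 30], 4)
        counts = pd.DataFrame([values], index=["g0"], columns=meta.index)
        sf = pd.Series(1.0, index=meta.index)
        disp = pd.Series(0.05, index=counts.index)
        res = fit_contrast(counts, sf, None, disp, "jTV6_vs_mTV6", meta)
        assert np.isclose(res.loc["g0", "lfc"], 0.0, atol=1e-8)
        assert np.isclose(res.loc["g0", "p"], 1.0)

    def test_recovers_planted_lfc(self):
        cfg = synthetic.SimConfig(
            n_genes=400, n_reps=20, dispersion=0.05, frac_equivalent=0,
            frac_A=1.0, frac_B=0, a_effect=(2.0, 0.0), length_log_sd=0.0,
            baseline_log_sd=0.5, seed=7)
        counts, meta, truth = synthetic.simulate_counts(cfg)
        sf = compute_size_factors(counts)
        disp = estimate_dispersions(counts, sf, meta)
        res = fit_contrast(counts, sf, None, disp, "jTV6_vs_mTV6", meta)
        est = np.abs(res["lfc"]).mean()
        assert abs(est - 2.0) < 0.1

    def test_null_p_values_uniform(self):
        cfg = synthetic.SimConfig(
            n_genes=2000, dispersion=0.05, frac_equivalent=0, frac_A=0,
            frac_B=0, length_log_sd=0.0, seed=8)
        counts, meta, _ = synthetic.simulate_counts(cfg)
        sf = compute_size_factors(counts)
        disp = pd.Series(0.05, index=counts.index)
        res = fit_contrast(counts, sf, None, disp, "jTV6_vs_mTV6", meta)
        ks = stats.kstest(res["p"].dropna(), "uniform")
        assert ks.pvalue > 0.01

    def test_all_zero_rows_flagged_missing(self):
        meta = synthetic.sample_metadata(2)
        counts = pd.DataFrame(
            [[0] * len(meta), [10] * len(meta)], index=["gz", "g1"],
            columns=meta.index)
        sf = pd.Series(1.0, index=meta.index)
        disp = pd.Series(0.05, index=counts.index)
        res = fit_contrast(counts, sf, None, disp, "jTV1_vs_mTV1", meta)
        assert np.isnan(res.loc["gz", "p"])
        assert not np.isnan(res.loc["g1", "p"])

    def test_unknown_contrast_rejected(self):
        with pytest.raises(ValueError, match="unknown contrast"):
            fit_contrast(pd.DataFrame(), pd.Series(dtype=float), None,
                         pd.Series(dtype=float), "bogus",
                         synthetic.sample_metadata(2))


class TestAdjustBH:
    def test_hand_step_up_example(self):
        np.testing.assert_allclose(
            adjust_bh([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(adjust_bh([0.37]), [0.37])

    def test_all_ones_stay_one(self):
        np.testing.assert_allclose(adjust_bh([1.0, 1.0, 1.0]), 1.0)

    def test_nan_excluded_from_m(self):
        padj = adjust_bh([0.01, np.nan, 0.02])
        assert np.isnan(padj[1])
        np.testing.assert_allclose(padj[[0, 2]], adjust_bh([0.01, 0.02]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.5])

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_monotone_and_dominates_p(self, p):
        padj = adjust_bh(p)
        assert np.all(padj <= 1.0 + 1e-12)
        assert np.all(padj >= np.asarray(p) - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(padj[order]) >= -1e-12)


class TestRunDE:
    def test_recall_on_planted_tv6_genes(self, default_sim):
        counts, meta, ortho, truth = default_sim
        res = run_de(counts, meta, ortho, contrast="jTV6_vs_mTV6")
        sig = set(res.index[(res["padj"] < 0.05).fillna(False)])
        de_truth = truth.index[(truth["gene_class"] != "null")
                               & (truth["lfc_TV6"].abs() > 1.0)]
        recall = len(sig & set(de_truth)) / len(de_truth)
        assert recall >= 0.8

    def test_one_to_zero_excluded_from_interspecies(self, default_sim):
        counts, meta, ortho, _ = default_sim
        res = run_de(counts, meta, ortho, contrast="jTV6_vs_mTV6")
        zero = ortho.index[ortho["orthology_class"] == "one_to_zero"]
        assert not res.loc[zero, "tested"].any()
        res_intra = run_de(counts, meta, ortho, contrast="jTV6_vs_jTV1")
        assert res_intra.loc[zero, "tested"].sum() > 0

    def test_null_by_construction_intra_gene(self):
        # delta_vert + lfc_TV6 - lfc_TV1 = 0 for equivalent genes with
        # slope 1: intra-jerboa contrast must not flag them
        cfg = synthetic.SimConfig(
            n_genes=500, frac_equivalent=0.4, frac_A=0, frac_B=0,
            slope_b=1.0, resid_sd=0.0, delta_vert=0.0, seed=9)
        counts, meta, truth = synthetic.simulate_counts(cfg)
        res = run_de(counts, meta, None, contrast="jTV6_vs_jTV1")
        eq = truth.index[truth["gene_class"] == "equivalent"]
        frac_sig = (res.loc[eq, "padj"] < 0.05).mean()
        assert frac_sig < 0.02

    def test_padj_monotone_in_p(self, default_sim):
        counts, meta, ortho, _ = default_sim
        res = run_de(counts, meta, ortho, contrast="jTV1_vs_mTV1").dropna(
            subset=["p"])
        srt = res.sort_values("p")
        assert np.all(np.diff(srt["padj"].to_numpy()) >= -1e-12)

    def test_lfc_invariant_under_common_size_factor_rescaling(self):
        cfg = synthetic.SimConfig(n_genes=300, seed=10, length_log_sd=0.0)
        counts, meta, _ = synthetic.simulate_counts(cfg)
        sf = compute_size_factors(counts)
        disp = pd.Series(0.05, index=counts.index)
        res1 = fit_contrast(counts, sf, None, disp, "jTV6_vs_jTV1", meta)
        res2 = fit_contrast(counts, sf * 7.3, None, disp, "jTV6_vs_jTV1",
                            meta)
        d = (res1["lfc"] - res2["lfc"]).abs().dropna()
        assert d.max() < 1e-6

    def test_lfc_stable_under_one_sample_count_scaling(self):
        # rescaling one sample's counts (with its size factor absorbing the
        # scale) re-weights the per-group score equations, so estimates move
        # only within numerical noise of the fit, not materially
        cfg = synthetic.SimConfig(n_genes=300, seed=10, length_log_sd=0.0)
        counts, meta, _ = synthetic.simulate_counts(cfg)
        res1 = run_de(counts, meta, None, contrast="jTV6_vs_jTV1")
        scaled = counts.copy()
        sample = counts.columns[3]
        scaled[sample] = counts[sample] * 5
        sf1 = compute_size_factors(counts)
        sf2 = compute_size_factors(scaled)
        other = counts.columns[0]
        assert np.isclose((sf2[sample] / sf2[other])
                          / (sf1[sample] / sf1[other]), 5.0, rtol=1e-6)
        res2 = run_de(scaled, meta, None, contrast="jTV6_vs_jTV1")
        d = (res1["lfc"] - res2["lfc"]).abs().dropna()
        assert d.max() < 0.05
        assert d.median() < 0.005

    def test_length_invariance_of_interspecies_lfc(self, default_sim):
        counts, meta, ortho, _ = default_sim
        res1 = run_de(counts, meta, ortho, contrast="jTV6_vs_mTV6")
        gene = res1.dropna(subset=["lfc"]).index[0]
        ortho2 = ortho.copy()
        counts2 = counts.copy()
        jerboa_cols = meta.index[meta["species"] == "jerboa"]
        ortho2.loc[gene, "length_jerboa"] *= 2.0
        counts2.loc[gene, jerboa_cols] = counts.loc[gene, jerboa_cols] * 2
        res2 = run_de(counts2, meta, ortho2, contrast="jTV6_vs_mTV6")
        assert abs(res1.loc[gene, "lfc"] - res2.loc[gene, "lfc"]) < 1e-3


class TestPCA:
    def test_species_separate_on_pc1(self, default_sim):
        counts, meta, _, _ = default_sim
        sf = compute_size_factors(counts)
        scores, frac = pca_check(counts, sf)
        sign = np.sign(scores["PC1"])
        by_species = sign.groupby(meta["species"]).mean()
        assert set(np.sign(by_species)) == {-1.0, 1.0}

    def test_duplicate_samples_identical_scores(self):
        counts = pd.DataFrame(
            np.random.default_rng(0).poisson(50, (100, 4)),
            columns=["a", "b", "c", "d"])
        counts["b"] = counts["a"]
        sf = pd.Series(1.0, index=counts.columns)
        scores, _ = pca_check(counts, sf)
        np.testing.assert_allclose(scores.loc["a"], scores.loc["b"],
                                   atol=1e-8)

    def test_variance_fractions_valid(self, default_sim):
        counts, meta, _, _ = default_sim
        sf = compute_size_factors(counts)
        _, frac = pca_check(counts, sf, n_components=4)
        assert frac.sum() <= 1.0 + 1e-9
        assert np.all(np.diff(frac) <= 1e-12)

    def test_too_many_components_rejected(self):
        counts = pd.DataFrame(np.ones((10, 3)), columns=list("abc"))
        sf = pd.Series(1.0, index=counts.columns)
        with pytest.raises(ValueError):
            pca_check(counts, sf, n_components=5)
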