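"""Five-class compensation calling, block resampling, and the
distribution/variance/association analyses."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import dosagenet as d
from dosagenet import compensation as comp
from dosagenet import expression as ex


def result_from_lfc(lfc, sd=0.05, n=3, null_lfc=-1.0, seed=0):
    """ModeratedTestResult for given per-gene mean LFCs with iid noise."""
    rng = np.random.default_rng(seed)
    lfc = np.asarray(lfc, float)
    ratios = pd.DataFrame(rng.normal(0, sd, (len(lfc), n)))
    # center noise so per-gene means sit exactly at lfc
    ratios = ratios.sub(ratios.mean(axis=1), axis=0).add(pd.Series(lfc), axis=0)
    return ex.moderated_t(ratios, null_lfc=null_lfc)


class TestClassifier:
    def test_lfc_at_minus_one_is_non(self):
        lfc = np.concatenate([[-1.0], np.linspace(-0.4, 0.4, 30)])
        res = result_from_lfc(lfc, sd=0.02)
        calls, _ = comp.classify_compensation(res, seed=1)
        assert calls["class"].iloc[0] == "non"

    def test_lfc_zero_within_centered_band_is_full(self):
        lfc = np.concatenate([[0.0], np.linspace(-0.3, 0.3, 30)])
        res = result_from_lfc(lfc, sd=0.02)
        calls, cut = comp.classify_compensation(res, seed=1)
        assert cut.lower < 0 < cut.upper
        assert calls["class"].iloc[0] == "full"

    def test_partition_every_gene_exactly_one_class(self, small_study):
        m = small_study.expression
        det = ex.detection_mask(m)["female"]
        ref = ex.build_reference(m, "parental", "female")
        res, lines = comp.one_dose_moderated_test(
            m, small_study.deficiencies, ref, "female", det
        )
        calls, cut = comp.classify_compensation(res, seed=2, lines=lines, sex="female")
        assert len(calls) == len(res.table)
        assert calls["class"].isin(["anti", "non", "partial", "full", "over"]).all()
        assert int(calls["class"].value_counts().sum()) == len(calls)
        # decision-rule consistency
        anti = calls[calls["class"] == "anti"]
        assert (anti["q"] < 0.05).all() and (anti["lfc"] < -1).all()
        non = calls[calls["class"] == "non"]
        assert (non["q"] >= 0.05).all()

    def test_band_widens_with_noise(self):
        uppers = []
        for sd in (0.1, 0.25, 0.5):
            rng = np.random.default_rng(3)
            lfc = rng.normal(-0.2, sd, 300)  # step-2-like spread grows with sd
            res = result_from_lfc(np.concatenate([lfc, np.full(50, -1.8)]), sd=0.05, seed=4)
            _, cut = comp.classify_compensation(res, seed=5)
            uppers.append(cut.upper)
        assert uppers[0] < uppers[1] < uppers[2]

    def test_boundary_tie_assigned_full(self):
        lfc = np.linspace(-0.5, 0.5, 40)
        res = result_from_lfc(lfc, sd=0.02, seed=6)
        calls, cut = comp.classify_compensation(res, seed=6)
        on_band = calls[np.isclose(calls["lfc"], cut.upper)]
        assert (on_band["class"] == "full").all()  # vacuous unless a tie lands

        # explicit tie: plant a gene exactly at the upper cutoff
        tab = res.table.copy()
        tab.loc[tab.index[0], "lfc"] = cut.upper
        res2 = ex.ModeratedTestResult(tab, res.d0, res.s0_sq, res.null_lfc)
        calls2, cut2 = comp.classify_compensation(res2, seed=6)
        g = tab.index[0]
        if np.isclose(cut2.upper, calls2.loc[g, "lfc"]):
            assert calls2.loc[g, "class"] == "full"

    def test_too_few_step2_genes_all_partial_with_warning(self):
        lfc = np.concatenate([np.full(30, -1.0), [-0.3, -0.2]])
        res = result_from_lfc(lfc, sd=0.02, seed=7)
        with pytest.warns(UserWarning, match="fewer than 10"):
            calls, cut = comp.classify_compensation(res, seed=7)
        step2 = calls[(calls["q"] < 0.05) & (calls["lfc"] > -1)]
        assert (step2["class"] == "partial").all()

    def test_requires_two_fold_null(self):
        res = result_from_lfc([-0.5, 0.0], null_lfc=0.0)
        with pytest.raises(ValueError):
            comp.classify_compensation(res)

    def test_step1_classes_recovered_on_planted_data(self):
        """anti and non (step-1 classes) and full recover well on planted
        data with isolated replicate noise."""
        s = d.generate_study(n_genes=400, genes_per_df=9, coexpression_weight=0.0, seed=8)
        m = s.expression
        det = ex.detection_mask(m)["female"]
        ref = ex.build_reference(m, "parental", "female")
        res, lines = comp.one_dose_moderated_test(m, s.deficiencies, ref, "female", det)
        calls, _ = comp.classify_compensation(res, seed=8, lines=lines, sex="female")
        truth = s.truth.gene_class.reindex(calls.index)
        for cls, floor in (("anti", 0.6), ("non", 0.6), ("full", 0.85)):
            mask = truth == cls
            if mask.sum() >= 5:
                assert (calls.loc[mask, "class"] == cls).mean() >= floor


class TestBlockResample:
    def order(self, n, rng=None):
        vals = pd.Series((rng or np.random.default_rng(0)).normal(0, 1, n),
                         index=[f"g{i:04d}" for i in range(n)])
        return vals

    def test_block_equal_to_all_genes_gives_identical_draws(self):
        vals = self.order(20)
        eligible = pd.Series(True, index=vals.index)
        out = comp.block_resample(vals, eligible, block_size=20, n_draws=50, seed=1)
        assert out["mean"].nunique() == 1
        assert out["mean"].iloc[0] == pytest.approx(vals.mean())

    def test_law_of_large_numbers(self):
        vals = self.order(500)
        eligible = pd.Series(True, index=vals.index)
        out = comp.block_resample(vals, eligible, block_size=25, n_draws=4000, seed=2)
        # draw means concentrate near the global mean
        assert out["mean"].mean() == pytest.approx(vals.mean(), abs=0.08)

    def test_se_scales_with_inverse_sqrt_draws(self):
        vals = self.order(500)
        eligible = pd.Series(True, index=vals.index)
        ses = []
        for n_draws in (200, 3200):
            means = [
                comp.block_resample(vals, eligible, 25, n_draws, seed=s)["mean"].mean()
                for s in range(20)
            ]
            ses.append(np.std(means, ddof=1))
        ratio = ses[0] / ses[1]
        assert ratio == pytest.approx(4.0, rel=0.5)  # sqrt(3200/200) = 4

    def test_reproducible_and_contiguity_respected(self):
        vals = self.order(60)
        eligible = pd.Series(True, index=vals.index)
        eligible.iloc[20:25] = False  # a one-dose region breaks contiguity
        a = comp.block_resample(vals, eligible, 10, 100, seed=3)
        b = comp.block_resample(vals, eligible, 10, 100, seed=3)
        pd.testing.assert_frame_equal(a, b)
        # no block may straddle the ineligible run
        for start in a["start"].unique():
            assert eligible.iloc[start : start + 10].all()

    def test_error_when_block_too_large(self):
        vals = self.order(10)
        eligible = pd.Series([True] * 5 + [False] + [True] * 4, index=vals.index)
        with pytest.raises(ValueError):
            comp.block_resample(vals, eligible, 6, 10)


class TestDistributionTests:
    def test_identical_samples_ks_one(self):
        rng = np.random.default_rng(4)
        x = rng.normal(-0.7, 0.4, 200)
        out = comp.distribution_tests(x, x.copy())
        assert out["ks_stat"] == pytest.approx(0.0)
        assert out["ks_p"] == pytest.approx(1.0)
        assert out["mean_fold_reduction"] == pytest.approx(2.0 ** (-x.mean()))

    def test_exponential_sample_rejected_by_jarque_bera(self):
        rng = np.random.default_rng(5)
        x = rng.exponential(1.0, 1000)
        out = comp.distribution_tests(x, rng.normal(0, 1, 1000))
        assert out["jarque_bera_p"] < 0.01

    def test_jarque_bera_type_one_calibrated(self):
        rng = np.random.default_rng(6)
        n_sims, alpha = 400, 0.05
        rej = sum(
            stats.jarque_bera(rng.normal(0, 1, 1000)).pvalue < alpha
            for _ in range(n_sims)
        )
        ci = 3 * np.sqrt(alpha * (1 - alpha) / n_sims)
        assert abs(rej / n_sims - alpha) < ci + 0.02

    def test_requires_minimum_sizes(self):
        with pytest.raises(ValueError):
            comp.distribution_tests([0.0] * 5, [0.0] * 100)


class TestVarianceComparison:
    def test_identical_sets_no_difference(self):
        rng = np.random.default_rng(7)
        x = pd.Series(rng.normal(-1, 0.5, 80), index=[f"g{i}" for i in range(80)])
        out = comp.variance_comparison(x, x.copy(), n_draws=500, seed=8)
        assert out["median_difference"] == pytest.approx(0.0)
        assert out["one_dose"]["median"] == pytest.approx(out["two_dose"]["median"])

    def test_planted_equal_variance_ci_covers_zero(self):
        # both states carry the same spread (the two-dose values are a
        # permutation of the one-dose values): no variance difference
        rng = np.random.default_rng(9)
        idx = [f"g{i}" for i in range(120)]
        a = pd.Series(rng.normal(-1.0, 0.4, 120), index=idx)
        b = pd.Series(rng.permutation(a.to_numpy()), index=idx)
        out = comp.variance_comparison(a - a.mean(), b - b.mean(), n_draws=1000, seed=10)
        assert out["difference_ci"]["ci_low"] <= 0 <= out["difference_ci"]["ci_high"]

    def test_doubled_noise_detected(self):
        rng = np.random.default_rng(11)
        idx = [f"g{i}" for i in range(150)]
        a = pd.Series(rng.normal(0, 0.8, 150), index=idx)
        b = pd.Series(rng.normal(0, 0.4, 150), index=idx)
        out = comp.variance_comparison(a, b, n_draws=1000, seed=12)
        assert out["difference_ci"]["ci_low"] > 0


class TestAssociations:
    def test_level_dependent_compensation_recovered(self):
        rng = np.random.default_rng(13)
        idx = [f"g{i}" for i in range(200)]
        level = pd.Series(rng.uniform(4, 14, 200), index=idx)
        lfc = pd.Series(-0.08 * level + rng.normal(0, 0.15, 200), index=idx)
        out = comp.compensation_vs_expression(lfc, level)
        assert out["rho"] < -0.5 and out["p"] < 0.01
        trend = out["trend"]["lfc_mean"]
        assert trend.iloc[-1] < trend.iloc[0]

    def test_constant_levels_flagged_degenerate(self):
        idx = [f"g{i}" for i in range(20)]
        out = comp.compensation_vs_expression(
            pd.Series(np.linspace(-1, 0, 20), index=idx),
            pd.Series(8.0, index=idx),
        )
        assert out["degenerate"] and np.isnan(out["rho"])

    def test_level_independent_null_calibrated(self):
        rng = np.random.default_rng(14)
        n_sims, alpha = 200, 0.05
        idx = [f"g{i}" for i in range(60)]
        rej = 0
        for _ in range(n_sims):
            level = pd.Series(rng.uniform(4, 14, 60), index=idx)
            lfc = pd.Series(rng.normal(-0.5, 0.3, 60), index=idx)
            if comp.compensation_vs_expression(lfc, level)["p"] < alpha:
                rej += 1
        ci = 3 * np.sqrt(alpha * (1 - alpha) / n_sims)
        assert abs(rej / n_sims - alpha) < ci + 0.02

    def test_sex_concordance_extremes_and_planted_ordering(self):
        rng = np.random.default_rng(15)
        idx = [f"g{i}" for i in range(300)]
        bias = pd.Series(
            ["none"] * 100 + ["female"] * 100 + ["male"] * 100, index=idx
        )
        shared = pd.Series(rng.normal(-0.5, 0.4, 300), index=idx)
        sex_sd = bias.map({"none": 0.1, "female": 0.5, "male": 0.5}).astype(float)
        f = shared + rng.normal(0, sex_sd)
        m = shared + rng.normal(0, sex_sd)
        out = comp.sex_concordance(f, m, bias)
        assert out.loc["none", "rho"] > out.loc["female", "rho"]
        assert out.loc["none", "rho"] > out.loc["male", "rho"]
        # identical ratios -> rho 1; independent -> near 0
        same = comp.sex_concordance(f, f, bias)
        assert same.loc["none", "rho"] == pytest.approx(1.0)
        indep = comp.sex_concordance(
            pd.Series(rng.normal(0, 1, 300), index=idx),
            pd.Series(rng.normal(0, 1, 300), index=idx),
            bias,
        )
        assert abs(indep.loc["none", "rho"]) < 0.35

    def test_small_group_reported_na(self):
        idx = [f"g{i}" for i in range(6)]
        bias = pd.Series(["none"] * 3 + ["female"] * 3, index=idx)
        out = comp.sex_concordance(
            pd.Series(np.arange(6.0), index=idx),
            pd.Series(np.arange(6.0), index=idx),
            bias,
        )
        assert np.isnan(out.loc["female", "rho"])


class TestCrossDfConsistency:
    def test_shared_effect_not_flagged_and_line_specific_detected(self, small_study):
        m = small_study.expression
        ref = ex.build_reference(m, "parental", "female")
        out = comp.cross_df_consistency(m, small_study.deficiencies, ref, "female")
        shared = {
            g
            for i, a in enumerate(small_study.deficiencies)
            for b in small_study.deficiencies[i + 1 :]
            for g in set(a.one_dose_genes) & set(b.one_dose_genes)
        }
        assert set(out.index) == shared
        # the generator plants the same effect in every line: mostly consistent
        assert out["significant"].mean() < 0.3

    def test_planted_line_specific_effect_detected(self, small_study):
        m = small_study.expression
        ref = ex.build_reference(m, "parental", "female")
        values = m.values.copy()
        # pick one shared gene and corrupt it in a single line
        out0 = comp.cross_df_consistency(m, small_study.deficiencies, ref, "female")
        g = out0.index[0]
        lines = [
            df.name for df in small_study.deficiencies if g in df.one_dose_genes
        ]
        ids = m.line_samples(lines[0], "female")
        values.loc[g, ids] += 2.5
        m2 = d.ExpressionMatrix(values, m.samples, m.features)
        out = comp.cross_df_consistency(m2, small_study.deficiencies, ref, "female")
        assert bool(out.loc[g, "significant"])

    def test_no_overlap_returns_empty(self):
        m = d.generate_study(n_genes=60, n_lines=2, genes_per_df=1, seed=16)
        # lines 1 and 2 are forced to overlap by the generator; drop one line
        dfs = [m.deficiencies[0]]
        ref = ex.build_reference(m.expression, "parental", "female")
        out = comp.cross_df_consistency(m.expression, dfs, ref, "female")
        assert out.empty


class TestExtentPosition:
    def test_constant_proportions_show_no_association(self, small_study):
        calls = pd.DataFrame(
            {"class": "non"},
            index=pd.Index(
                sorted({g for df in small_study.deficiencies for g in df.one_dose_genes})
            ),
        )
        out = comp.extent_position_association(calls, small_study.deficiencies)
        assert out[out["class"] == "non"]["rho"].abs().fillna(0).max() < 1e-9 or (
            out[out["class"] == "non"]["rho"].isna().all()
        )

    def test_planted_extent_dependence_detected(self, small_study):
        dfs = small_study.deficiencies
        rows = {}
        extents = np.array([df.extent_bp for df in dfs])
        median_ext = np.median(extents)
        for df in dfs:
            cls = "anti" if df.extent_bp > median_ext else "full"
            for g in df.one_dose_genes:
                rows[g] = cls
        calls = pd.DataFrame({"class": pd.Series(rows)})
        out = comp.extent_position_association(calls, dfs)
        row = out[(out["class"] == "anti") & (out["covariate"] == "extent_bp")].iloc[0]
        assert row["rho"] > 0.6 and row["p"] < 0.01

    def test_requires_five_deficiencies(self, small_study):
        calls = pd.DataFrame({"class": []})
        with pytest.raises(ValueError):
            comp.extent_position_association(calls, small_study.deficiencies[:3])
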