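"""Normalization, expression filtering, the NB GLM, its controls and the
saturation bootstrap."""

import numpy as np
import pandas as pd
import pytest

from xydosage import dosage_model as dm
from xydosage import synthetic_data as sd


class TestSizeFactors:
    def test_hand_computed_median_of_ratios(self):
        counts = pd.DataFrame(
            {"s1": [10, 20, 40], "s2": [20, 80, 40]},
            index=["g1", "g2", "g3"],
        )
        # geometric means: sqrt(200), sqrt(1600), 40
        # ratios s1: 10/14.142, 20/40, 40/40 -> median 0.70711
        # ratios s2: 20/14.142, 80/40, 40/40 -> median 1.41421
        sf = dm.size_factors(counts)
        expect = np.array([10 / np.sqrt(200), np.sqrt(2)])
        expect = expect / np.exp(np.mean(np.log(expect)))
        np.testing.assert_allclose(sf.factors.to_numpy(), expect, rtol=1e-12)

    def test_doubling_a_sample_doubles_its_factor(self, small_counts):
        doubled = small_counts.copy()
        doubled["s0000"] = doubled["s0000"] * 2
        a = dm.size_factors(small_counts).factors
        b = dm.size_factors(doubled).factors
        assert b["s0000"] / a["s0000"] == pytest.approx(2 ** (105 / 106), rel=1e-9)

    def test_identical_samples_give_unit_factors(self):
        counts = pd.DataFrame(np.tile([[5], [9], [3]], (1, 4)), index=list("abc"))
        np.testing.assert_allclose(dm.size_factors(counts).factors, 1.0)

    def test_geometric_mean_is_one(self, small_counts):
        f = dm.size_factors(small_counts).factors.to_numpy()
        assert np.mean(np.log(f)) == pytest.approx(0.0, abs=1e-12)

    def test_no_zero_free_gene_is_an_error(self):
        counts = pd.DataFrame({"s1": [0, 1], "s2": [1, 0]}, index=["g1", "g2"])
        with pytest.raises(ValueError, match="pseudo-reference"):
            dm.size_factors(counts)


class TestTPM:
    def test_single_gene_is_a_million(self):
        tpm = dm.compute_tpm(pd.DataFrame({"s": [7]}, index=["g"]), pd.Series({"g": 100}))
        assert tpm.loc["g", "s"] == pytest.approx(1e6)

    def test_length_normalization_split(self):
        counts = pd.DataFrame({"s": [10, 10]}, index=["g1", "g2"])
        tpm = dm.compute_tpm(counts, pd.Series({"g1": 100, "g2": 200}))
        np.testing.assert_allclose(tpm["s"], [2e6 / 3, 1e6 / 3])

    def test_columns_sum_to_a_million(self, small_counts, annotation):
        tpm = dm.compute_tpm(small_counts, annotation["length"])
        np.testing.assert_allclose(tpm.sum(axis=0), 1e6, rtol=1e-9)

    def test_zero_sample_named_in_error(self):
        counts = pd.DataFrame({"good": [1], "empty": [0]}, index=["g"])
        with pytest.raises(ValueError, match="empty"):
            dm.compute_tpm(counts, pd.Series({"g": 100}))


class TestFilterExpressed:
    @pytest.mark.parametrize(
        "med_xx,med_xy,kept",
        [(1.5, 0.0, True), (0.9, 0.9, False), (0.0, 5.0, True)],
    )
    def test_median_tpm_or_rule(self, med_xx, med_xy, kept):
        meta = pd.DataFrame(
            {"karyotype": ["46,XX"] * 3 + ["46,XY"] * 3},
            index=[f"s{i}" for i in range(6)],
        )
        tpm = pd.DataFrame([[med_xx] * 3 + [med_xy] * 3], index=["g"], columns=meta.index)
        result = dm.filter_expressed(tpm, meta)
        assert ("g" in result) == kept

    def test_missing_group_is_an_error(self):
        meta = pd.DataFrame({"karyotype": ["46,XX"]}, index=["s0"])
        tpm = pd.DataFrame([[2.0]], index=["g"], columns=["s0"])
        with pytest.raises(ValueError, match="46,XY"):
            dm.filter_expressed(tpm, meta)


class TestDesignMatrix:
    def test_rank_deficiency_detected(self):
        meta = pd.DataFrame({"x_copies": [1, 1, 2, 2], "xi_copies": [0, 0, 1, 1]})
        spec = dm.DesignSpec(numeric=("x_copies", "xi_copies"), coefficients=("x_copies",))
        with pytest.raises(ValueError, match="rank"):
            dm.build_design_matrix(meta, spec)

    def test_coefficient_must_be_numeric_covariate(self):
        with pytest.raises(ValueError):
            dm.DesignSpec(numeric=("x_copies",), coefficients=("y_copies",))


class TestFitDosageGLM:
    def test_constant_gene_null_fit(self, lcl_meta):
        counts = pd.DataFrame(
            np.full((3, len(lcl_meta)), 40), index=list("abc"), columns=lcl_meta.index
        )
        fit = dm.fit_dosage_glm(counts, lcl_meta)
        assert np.allclose(fit["log2fc_per_copy"], 0.0, atol=1e-6)
        assert (fit["p"] > 0.999).all()

    def test_agrees_with_log_linear_oracle_on_large_poisson(self, rng):
        # large-count Poisson: NB GLM estimates should match a log-linear
        # least-squares fit on log expected counts
        n = 120
        x = rng.integers(1, 5, n).astype(float)
        batch = rng.integers(0, 2, n)
        meta = pd.DataFrame(
            {"x_copies": x, "y_copies": rng.integers(0, 3, n), "batch": np.where(batch, "b2", "b1"),
             "chr21_copies": 2, "karyotype": "46,XX"},
            index=[f"s{i}" for i in range(n)],
        )
        beta = 0.4
        mu = 5000 * 2.0 ** (beta * x + 0.2 * batch)
        counts = pd.DataFrame(
            rng.poisson(np.tile(mu, (40, 1))), columns=meta.index,
            index=[f"g{i}" for i in range(40)],
        )
        fit = dm.fit_dosage_glm(
            counts, meta,
            dm.DesignSpec(("x_copies",), ("batch",), ("x_copies",)),
            sf=dm.SizeFactors(pd.Series(1.0, index=meta.index), counts.index),
        )
        # oracle: OLS of log2(counts) on the same design, gene by gene
        X = np.column_stack([np.ones(n), x, batch])
        for gid in counts.index[:10]:
            y = np.log2(counts.loc[gid].to_numpy())
            ols = np.linalg.lstsq(X, y, rcond=None)[0][1]
            est = fit.set_index("gene").loc[gid, "log2fc_per_copy"]
            assert est == pytest.approx(ols, abs=0.02)

    def test_parameter_recovery_on_synthetic_truth(self, small_counts, lcl_meta, small_truth, small_fit):
        fx = small_fit[small_fit["coef"] == "x_copies"].set_index("gene")
        resp = small_truth.genes["x_responsive"]
        err = (fx["log2fc_per_copy"] - small_truth.genes["beta_x"]).abs()
        assert err[resp].median() < 0.1

    def test_sample_scaling_absorbed_by_size_factors(self, small_counts, lcl_meta):
        # the size factor absorbs a rescaled sample up to the NB weight
        # change of a raw-count GLM (the sample's likelihood contribution
        # grows with its depth); the residual effect on estimates is tiny
        scaled = small_counts.copy()
        scaled.iloc[:, 0] = scaled.iloc[:, 0] * 8
        a = dm.fit_dosage_glm(small_counts, lcl_meta)
        b = dm.fit_dosage_glm(scaled, lcl_meta)
        d = np.abs(
            a[a.coef == "x_copies"]["log2fc_per_copy"].to_numpy()
            - b[b.coef == "x_copies"]["log2fc_per_copy"].to_numpy()
        )
        assert d.max() < 5e-3
        assert np.median(d) < 1e-4

    def test_centering_covariates_leaves_estimates_unchanged(self, small_counts, lcl_meta):
        centered = lcl_meta.copy()
        centered["x_copies"] = centered["x_copies"] - centered["x_copies"].mean()
        centered["y_copies"] = centered["y_copies"] - centered["y_copies"].mean()
        a = dm.fit_dosage_glm(small_counts, lcl_meta)
        b = dm.fit_dosage_glm(small_counts, centered)
        np.testing.assert_allclose(
            a["log2fc_per_copy"].to_numpy(), b["log2fc_per_copy"].to_numpy(), atol=1e-6
        )

    def test_bh_is_monotone_and_bounded(self, small_fit):
        grp = small_fit[small_fit["coef"] == "x_copies"].sort_values("p")
        padj = grp["padj"].to_numpy()
        assert (padj[np.argsort(grp["p"].to_numpy())] == np.sort(padj)).all()
        assert (padj <= 1).all() and (padj >= grp["p"].to_numpy() - 1e-15).all()

    def test_degenerate_coefficient_rejected(self, small_counts, lcl_meta):
        meta = lcl_meta[lcl_meta["karyotype"] == "46,XX"]
        with pytest.raises(ValueError, match="x_copies"):
            dm.fit_dosage_glm(small_counts[meta.index], meta)


class TestAlternativeDesigns:
    def test_trisomy21_recovery(self):
        entries = [
            sd.KaryotypeEntry("46,XX", 2, 0, 2, 20),
            sd.KaryotypeEntry("46,XY", 1, 1, 2, 20),
            sd.KaryotypeEntry("47,XX+21", 2, 0, 3, 10),
            sd.KaryotypeEntry("47,XY+21", 1, 1, 3, 10),
        ]
        design = sd.KaryotypeDesign(entries=tuple(entries))
        meta = sd.generate_design(design, seed=20)
        meta["sex"] = np.where(meta["y_copies"] > 0, "XY", "XX")
        truth = sd.generate_truth(400, 0.0, 0.0, 0.0, frac_21_responsive=0.3, seed=21)
        counts = sd.generate_counts(meta, truth, seed=22)
        spec = dm.DesignSpec(("chr21_copies",), ("sex", "batch"), ("chr21_copies",))
        fit = dm.fit_alternative_designs(counts, meta, spec).set_index("gene")
        resp = truth.genes["beta_21"] != 0
        err = (fit["log2fc_per_copy"] - truth.genes["beta_21"]).abs()
        assert err[resp].median() < 0.1

    def test_knockdown_effect_on_target_gene(self, rng):
        # target gene reduced to 20% in knockdown samples
        n = 60
        kd = np.repeat([0, 1], n // 2)
        meta = pd.DataFrame(
            {"kd": kd.astype(float), "cell_line": np.tile(["c1", "c2", "c3"], n // 3)},
            index=[f"s{i}" for i in range(n)],
        )
        mu = np.where(kd == 1, 0.2 * 2000, 2000)
        counts = pd.DataFrame(
            rng.poisson(np.tile(mu, (20, 1))), columns=meta.index,
            index=[f"g{i}" for i in range(20)],
        )
        counts.iloc[1:] = rng.poisson(800, size=(19, n))  # unaffected genes
        spec = dm.DesignSpec(("kd",), ("cell_line",), ("kd",))
        fit = dm.fit_alternative_designs(
            counts, meta, spec,
            sf=dm.SizeFactors(pd.Series(1.0, index=meta.index), counts.index),
        )
        est = fit.set_index("gene").loc["g0", "log2fc_per_copy"]
        assert est == pytest.approx(np.log2(0.2), abs=0.1)


class TestRenormalizationControl:
    def test_identity_when_no_sex_linked_genes(self, small_counts, lcl_meta, small_truth):
        ann = sd.generate_annotation(small_truth, seed=30, frac_x_linked=0.0, frac_y_linked=0.0)
        res = dm.renormalization_control(small_counts, lcl_meta, ann)
        assert max(res.max_abs_diff.values()) < 1e-12

    def test_default_simulation_virtually_identical(self, small_counts, lcl_meta, annotation):
        res = dm.renormalization_control(small_counts, lcl_meta, annotation)
        assert res.pearson_r["x_copies"] > 0.99

    def test_adversarial_imbalance_reported_not_suppressed(self, lcl_meta):
        truth = sd.generate_truth(200, 0.0, 0.0, 0.0, seed=31, batch_sd=0.0)
        counts = sd.generate_counts(lcl_meta, truth, seed=32)
        ann = sd.generate_annotation(truth, seed=33, frac_x_linked=0.5, frac_y_linked=0.0)
        # make the X-linked half dosage-dependent and huge so normalization shifts
        xg = ann.index[ann["chrom"] == "chrX"]
        factor = 20.0 * lcl_meta["x_copies"].to_numpy()
        counts.loc[xg] = (counts.loc[xg] * factor).astype(int)
        res = dm.renormalization_control(counts, lcl_meta, ann)
        assert max(res.max_abs_diff.values()) > 0.01


class TestSaturation:
    def test_full_size_single_rep_matches_full_analysis(self, small_counts, lcl_meta, small_fit):
        sat = dm.saturation_bootstrap(
            small_counts, lcl_meta, sizes=(len(lcl_meta),), reps=1, seed=40
        )
        for coef, grp in small_fit.groupby("coef"):
            full = int((grp["padj"] < 0.05).sum())
            got = sat[sat["coef"] == coef]["n_significant"].iloc[0]
            assert got == full

    def test_row_bookkeeping(self, small_counts, lcl_meta):
        sat = dm.saturation_bootstrap(small_counts, lcl_meta, sizes=(20,), reps=7, seed=41)
        assert len(sat) == 7 * 2  # two coefficients of interest
        assert sat["ok"].all()

    def test_degenerate_subset_recorded_as_missing(self):
        meta = pd.DataFrame(
            {
                "karyotype": ["46,XX"] * 7 + ["46,XY", "47,XYY", "47,XXY"],
                "x_copies": [2] * 7 + [1, 1, 2],
                "y_copies": [0] * 7 + [1, 2, 1],
                "chr21_copies": 2,
                "batch": "b1",
            },
            index=[f"s{i}" for i in range(10)],
        )
        truth = sd.generate_truth(50, 0, 0, 0, batches=("b1",), seed=42)
        counts = sd.generate_counts(meta, truth, seed=43)
        spec = dm.DesignSpec(("x_copies", "y_copies"), (), ("x_copies", "y_copies"))
        sat = dm.saturation_bootstrap(counts, meta, spec, sizes=(4,), reps=20, seed=44)
        assert len(sat) == 40
        assert (~sat["ok"]).any()
        assert sat.loc[~sat["ok"], "n_significant"].isna().all()

    def test_oversized_subset_rejected(self, small_counts, lcl_meta):
        with pytest.raises(ValueError, match="exceeds"):
            dm.saturation_bootstrap(small_counts, lcl_meta, sizes=(500,), reps=1)
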