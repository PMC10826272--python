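"""Noise modelling, replicate merging and the wBC/RSN normalization pair."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from autoreact.preprocess import (
    detect_empty_outliers,
    noise_thresholds,
    preprocess_pipeline,
    robust_spline_normalize,
    validate_and_merge,
    weighted_boxcox,
)
from autoreact.simdata import SimConfig, generate_bead_array

from conftest import make_manual_dataset


def dataset_with_empty_means(means, n_empty=2, sample_rows=None):
    """Manual dataset whose per-analyte empty-well means equal `means`."""
    means = np.asarray(means, float)
    n_analytes = len(means)
    sample_rows = sample_rows if sample_rows is not None else [
        list(means * 50.0), list(means * 60.0), list(means * 55.0), list(means * 45.0)
    ]
    empty_rows = [list(means)] * n_empty
    rep = np.array(sample_rows + empty_rows)
    roles = ["sample"] * len(sample_rows) + ["empty"] * n_empty
    groups = (["case", "control"] * len(sample_rows))[: len(sample_rows)] + [None] * n_empty
    return make_manual_dataset(rep, rep.copy(), roles, groups)


class TestEmptyOutliers:
    def test_hand_computed_flagging(self):
        # m = [10,11,12,100]: median 11.5, sample SD 44.51 -> only analyte 4
        ds = dataset_with_empty_means([10, 11, 12, 100])
        assert detect_empty_outliers(ds) == {"A4"}

    def test_tight_means_with_top_value_just_over(self):
        # m = [10,11,12,13]: SD ~ 1.29, median 11.5 -> 13 > 12.79 flagged
        ds = dataset_with_empty_means([10, 11, 12, 13])
        assert detect_empty_outliers(ds) == {"A4"}

    def test_equal_means_flag_nothing(self):
        ds = dataset_with_empty_means([10, 10, 10, 10])
        assert detect_empty_outliers(ds) == set()

    def test_requires_two_empty_wells(self):
        ds = dataset_with_empty_means([10, 11, 12, 13], n_empty=1)
        with pytest.raises(ValueError, match="empty wells"):
            detect_empty_outliers(ds)


class TestNoiseThresholds:
    def test_max_plus_sd_of_pool(self):
        # one analyte, three empty wells with readings 5, 6, 7: SD = 1 -> 8
        rep = np.array([[100.0], [90.0], [5.0], [6.0], [7.0]])
        ds = make_manual_dataset(
            rep, rep.copy(), ["sample", "sample", "empty", "empty", "empty"],
            ["case", "control", None, None, None],
        )
        noise = noise_thresholds(ds, outliers=set())
        assert noise.threshold_rep1 == pytest.approx(8.0)
        assert noise.excluded_analytes == set()

    def test_boundary_is_strictly_above(self):
        # sample max exactly at the threshold -> excluded
        rep = np.array([[8.0], [7.5], [5.0], [6.0], [7.0]])
        ds = make_manual_dataset(
            rep, rep.copy(), ["sample", "sample", "empty", "empty", "empty"],
            ["case", "control", None, None, None],
        )
        noise = noise_thresholds(ds, outliers=set())
        assert noise.excluded_analytes == {"A1"}

    def test_all_noise_analytes_excluded_in_both_replicates(self):
        ds = generate_bead_array(SimConfig(n_analytes=40, seed=21))
        # force two analytes to pure background in both replicates
        for col in ("AF0005", "AF0017"):
            ds.mfi_rep1.loc[ds.sample_wells, col] = 1.0
            ds.mfi_rep2.loc[ds.sample_wells, col] = 1.0
        noise = noise_thresholds(ds, detect_empty_outliers(ds))
        assert {"AF0005", "AF0017"} <= noise.excluded_analytes
        assert noise.excluded_analytes == noise.excluded_rep1 & noise.excluded_rep2

    def test_either_rule_is_superset_of_both_rule(self):
        ds = generate_bead_array(SimConfig(n_analytes=60, seed=22))
        out = detect_empty_outliers(ds)
        both = noise_thresholds(ds, out, rule="both").excluded_analytes
        either = noise_thresholds(ds, out, rule="either").excluded_analytes
        assert both <= either

    def test_exclusion_monotone_in_threshold(self):
        ds = generate_bead_array(SimConfig(n_analytes=80, seed=23))
        samples = ds.sample_wells
        noise = noise_thresholds(ds, set())
        thr = noise.threshold_rep1
        def excluded_at(t):
            above = (ds.mfi_rep1.loc[samples] > t).any(axis=0)
            return set(above.index[~above])
        assert excluded_at(thr) <= excluded_at(thr * 1.5)


class TestValidateAndMerge:
    def test_mean_then_background_subtraction(self):
        rep1 = np.array([[10.0], [30.0], [5.0], [5.0]])
        rep2 = np.array([[20.0], [40.0], [5.0], [5.0]])
        ds = make_manual_dataset(
            rep1, rep2, ["sample", "sample", "empty", "empty"],
            ["case", "control", None, None],
        )
        noise = noise_thresholds(ds, set())
        clean = validate_and_merge(ds, noise)
        # merged (10+20)/2 = 15, minus empty mean 5 -> 10
        assert clean.values.iloc[0, 0] == pytest.approx(10.0)
        assert clean.values.iloc[1, 0] == pytest.approx(30.0)

    def test_empty_wells_center_at_zero_after_subtraction(self, small_dataset):
        noise = noise_thresholds(small_dataset, detect_empty_outliers(small_dataset))
        clean_all = validate_and_merge(small_dataset, noise, wells="all")
        empties = small_dataset.wells_with_role("empty")
        np.testing.assert_allclose(
            clean_all.values.loc[empties].mean(axis=0).to_numpy(), 0.0, atol=1e-9
        )

    def test_discordant_replicate_pairs_flagged_not_removed(self, small_dataset):
        ds = small_dataset
        rep1 = ds.mfi_rep1.copy()
        well, col = ds.sample_wells[0], ds.analytes[0]
        rep1.loc[well, col] *= 40.0  # one wildly discordant reading
        import dataclasses
        tampered = dataclasses.replace(ds, mfi_rep1=rep1)
        noise = noise_thresholds(tampered, detect_empty_outliers(tampered))
        clean = validate_and_merge(tampered, noise)
        if col in clean.values.columns:
            assert bool(clean.provenance.loc[well, col])
            expected = (rep1.loc[well, col] + ds.mfi_rep2.loc[well, col]) / 2 - \
                noise.empty_means[col]
            assert clean.values.loc[well, col] == pytest.approx(expected)


class TestWeightedBoxCox:
    def test_lambda_one_is_affine_identity(self):
        x = np.linspace(1, 10, 12)
        from autoreact.preprocess import _boxcox_transform
        np.testing.assert_allclose(_boxcox_transform(x, 1.0), x - 1.0)

    def test_lambda_zero_branch_is_log(self):
        x = np.linspace(1, 10, 12)
        from autoreact.preprocess import _boxcox_transform
        np.testing.assert_allclose(_boxcox_transform(x, 1e-6), np.log(x))

    def test_lognormal_data_estimates_lambda_near_zero(self):
        """Average lambda-hat over 100 independent draws of n = 60 from a
        log-normal stays within 0.15 of the log transform's 0."""
        rng = np.random.default_rng(77)
        X = pd.DataFrame(rng.lognormal(5.0, 0.5, size=(60, 100)))
        res = weighted_boxcox(X)
        assert abs(float(res.lambdas.mean())) < 0.15

    def test_matches_scipy_mle_with_unit_weights(self):
        rng = np.random.default_rng(5)
        x = rng.gamma(4.0, 10.0, 60)
        ours = float(weighted_boxcox(pd.DataFrame({"a": x})).lambdas.iloc[0])
        ref = float(stats.boxcox_normmax(x, method="mle"))
        assert ours == pytest.approx(ref, abs=0.02)

    def test_constant_analyte_flagged_with_lambda_one(self):
        X = pd.DataFrame({"a": np.full(10, 3.0), "b": np.arange(10.0) + 1})
        with pytest.warns(UserWarning, match="constant"):
            res = weighted_boxcox(X)
        assert res.lambdas["a"] == 1.0
        assert res.constant_analytes == {"a"}

    def test_weights_shift_the_estimate(self):
        rng = np.random.default_rng(8)
        x = np.concatenate([rng.lognormal(3, 0.4, 30), rng.gamma(20, 5, 30)])
        X = pd.DataFrame({"a": x})
        w_first = np.r_[np.ones(30), np.zeros(30) + 1e-12]
        lam_first = float(weighted_boxcox(X, weights=w_first).lambdas.iloc[0])
        lam_all = float(weighted_boxcox(X).lambdas.iloc[0])
        assert lam_first != pytest.approx(lam_all, abs=1e-3)


class TestRobustSplineNormalize:
    def test_identity_on_identical_wells(self):
        row = np.sort(np.random.default_rng(1).lognormal(2, 0.8, 50))
        X = pd.DataFrame(np.tile(row, (6, 1)))
        out = robust_spline_normalize(X).values.to_numpy()
        assert np.max(np.abs(out - X.to_numpy())) < 1e-6

    def test_ranks_preserved_within_each_well(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(0, 1, size=(8, 120)) + rng.normal(0, 0.5, (8, 1)))
        out = robust_spline_normalize(X).values
        for i in range(8):
            a = X.iloc[i].rank(method="average")
            b = out.iloc[i].rank(method="average")
            s = stats.spearmanr(a, b).statistic
            assert s > 0.9999

    def test_idempotent_to_1e3_rms(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(0, 1, size=(10, 200)) * rng.uniform(0.5, 2, (10, 1)))
        once = robust_spline_normalize(X).values
        twice = robust_spline_normalize(once).values
        rms = float(np.sqrt(np.mean((twice.to_numpy() - once.to_numpy()) ** 2)))
        assert rms < 1e-3

    def test_shifted_well_converges_to_shared_reference(self):
        """Two wells offset by a constant meet at the per-rank median
        reference: each moves half the offset and they coincide."""
        rng = np.random.default_rng(4)
        a = np.sort(rng.normal(0, 1, 400))
        X = pd.DataFrame([a, a + 2.0])
        out = robust_spline_normalize(X).values.to_numpy()
        interior = slice(40, 360)
        np.testing.assert_allclose(out[0][interior], out[1][interior], atol=0.05)
        shift_b = out[1] - X.to_numpy()[1]
        assert np.median(shift_b[interior]) == pytest.approx(-1.0, abs=0.05)

    def test_too_few_analytes_falls_back_to_linear(self):
        X = pd.DataFrame(np.random.default_rng(6).normal(0, 1, size=(4, 5)))
        with pytest.warns(UserWarning, match="linear"):
            out = robust_spline_normalize(X, n_anchors=11)
        assert out.values.shape == X.shape


class TestPipelineOrder:
    def test_stages_compose_in_fixed_order(self, study_dataset):
        noise, clean, normalized = preprocess_pipeline(study_dataset)
        kept = [a for a in study_dataset.analytes if a not in noise.excluded_analytes]
        assert list(clean.values.columns) == kept
        assert list(normalized.values.columns) == kept
        assert list(clean.values.index) == list(study_dataset.sample_wells)
        assert not normalized.values.isna().any().any()

    def test_group_means_mostly_equal_under_null(self):
        """Zero-effect simulation: at most ~6% of analytes reach p < 0.05
        in a plain two-group comparison after full preprocessing."""
        from autoreact.simdata import null_config
        ds = generate_bead_array(null_config(SimConfig(seed=31), n_analytes=500))
        _, _, normalized = preprocess_pipeline(ds)
        groups = ds.groups()
        case = normalized.values.loc[groups.index[groups == "case"]].to_numpy()
        ctrl = normalized.values.loc[groups.index[groups == "control"]].to_numpy()
        p = stats.ttest_ind(case, ctrl, axis=0).pvalue
        assert (p >= 0.05).mean() >= 0.94
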