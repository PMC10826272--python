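"""Empirical-Bayes moderated testing, BH adjustment, fold changes and the
baseline cohort-table statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from autoreact.differential import (
    EBayesParams,
    bh_adjust,
    chisq_2x2,
    differential_table,
    estimate_variance_prior,
    fit_ebayes,
    fold_changes,
    moderated_t,
    unpaired_t,
)

from _oracles import bh_oracle, moderated_t_oracle, welch_t_oracle


def two_group_frame(rng, n1=15, n2=15, n_analytes=40, scale=None):
    scale = scale if scale is not None else np.ones(n_analytes)
    X = rng.standard_normal((n1 + n2, n_analytes)) * scale
    values = pd.DataFrame(X, index=[f"w{i}" for i in range(n1 + n2)])
    groups = pd.Series(["case"] * n1 + ["control"] * n2, index=values.index)
    return values, groups


class TestEBayesPrior:
    def test_identical_variances_give_infinite_prior_df(self):
        from scipy import special
        s2 = np.full(200, 0.37)
        d0, s0 = estimate_variance_prior(s2, df=28)
        assert math.isinf(d0)
        # The moment estimator assumes each s2 carries chi-square sampling
        # noise and corrects the log-scale bias, so the recovered prior is
        # s2 * exp(ln(d/2) - digamma(d/2)) — within ~4% of s2 at d = 28.
        expected = 0.37 * math.exp(math.log(14.0) - float(special.digamma(14.0)))
        assert s0 == pytest.approx(expected, rel=1e-9)
        assert s0 == pytest.approx(0.37, rel=0.05)
        params = EBayesParams(d0=d0, s0_sq=s0, s2=pd.Series(s2), df=28)
        np.testing.assert_allclose(params.posterior_var().to_numpy(), s0)

    def test_posterior_lies_between_prior_and_sample_variance(self):
        rng = np.random.default_rng(1)
        values, groups = two_group_frame(rng, scale=rng.uniform(0.5, 2.0, 40))
        params = fit_ebayes(values, groups)
        post = params.posterior_var()
        lo = np.minimum(params.s2, params.s0_sq)
        hi = np.maximum(params.s2, params.s0_sq)
        assert ((post >= lo - 1e-12) & (post <= hi + 1e-12)).all()

    def test_prior_recovery_from_simulated_variances(self):
        rng = np.random.default_rng(2)
        d0_true, s0_true, df = 4.0, 1.0, 58
        sigma2 = d0_true * s0_true / rng.chisquare(d0_true, 2000)
        s2 = sigma2 * rng.chisquare(df, 2000) / df
        d0, s0 = estimate_variance_prior(s2, df)
        assert d0 == pytest.approx(d0_true, abs=1.0)
        assert s0 == pytest.approx(s0_true, abs=0.15)

    def test_all_zero_variances_error(self):
        with pytest.raises(ValueError):
            estimate_variance_prior(np.zeros(10), df=8)


class TestModeratedT:
    def test_equal_group_means_give_t_zero_p_one(self):
        values = pd.DataFrame(
            {"a": [1.0, 2.0, 1.0, 2.0], "b": [3.0, 1.0, 3.0, 1.0]},
            index=["w1", "w2", "w3", "w4"],
        )
        groups = pd.Series(["case", "case", "control", "control"], index=values.index)
        params = fit_ebayes(values, groups)
        res = moderated_t(values, groups, params)
        np.testing.assert_allclose(res["t_mod"], 0.0, atol=1e-12)
        np.testing.assert_allclose(res["p_value"], 1.0)

    def test_d0_zero_limit_equals_classical_pooled_t(self):
        from scipy import stats
        rng = np.random.default_rng(3)
        values, groups = two_group_frame(rng)
        params = fit_ebayes(values, groups)
        zero = EBayesParams(d0=0.0, s0_sq=params.s0_sq, s2=params.s2, df=params.df)
        res = moderated_t(values, groups, zero)
        case = values[groups == "case"].to_numpy()
        ctrl = values[groups == "control"].to_numpy()
        classical = stats.ttest_ind(case, ctrl, axis=0, equal_var=True)
        np.testing.assert_allclose(res["t_mod"], classical.statistic, atol=1e-10)
        np.testing.assert_allclose(res["p_value"], classical.pvalue, atol=1e-10)

    def test_d0_inf_uses_prior_variance_everywhere(self):
        rng = np.random.default_rng(4)
        values, groups = two_group_frame(rng)
        params = fit_ebayes(values, groups)
        inf = EBayesParams(d0=math.inf, s0_sq=0.9, s2=params.s2, df=params.df)
        res = moderated_t(values, groups, inf)
        case = values[groups == "case"].to_numpy()
        ctrl = values[groups == "control"].to_numpy()
        expected = (case.mean(0) - ctrl.mean(0)) / np.sqrt(0.9 * (2 / 15))
        np.testing.assert_allclose(res["t_mod"], expected, atol=1e-12)

    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(5)
        scale = np.sqrt(0.5 * 4 / rng.chisquare(4, 30))
        values, groups = two_group_frame(rng, n1=20, n2=20, n_analytes=30, scale=scale)
        params = fit_ebayes(values, groups)
        res = moderated_t(values, groups, params)
        case = values[groups == "case"].to_numpy()
        ctrl = values[groups == "control"].to_numpy()
        d0_o, s0_o, t_o, p_o = moderated_t_oracle(case, ctrl)
        assert params.d0 == pytest.approx(d0_o, rel=1e-6)
        assert params.s0_sq == pytest.approx(s0_o, rel=1e-8)
        np.testing.assert_allclose(res["t_mod"], t_o, atol=1e-8)
        np.testing.assert_allclose(res["p_value"], p_o, atol=1e-8)


class TestBHAdjust:
    def test_hand_stepup_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.005, 0.01, 0.03, 0.04]), [0.02, 0.02, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.123]), [0.123])

    def test_na_propagates_without_affecting_others(self):
        out = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(out[1])
        np.testing.assert_allclose(out[[0, 2]], bh_adjust([0.01, 0.04]))

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.2, 1.4])

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60)
    )
    @settings(max_examples=60, deadline=None)
    def test_properties_and_naive_oracle(self, ps):
        p = np.array(ps)
        q = bh_adjust(p)
        assert (q >= p - 1e-15).all() and (q <= 1.0 + 1e-15).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()  # monotone in sorted order
        np.testing.assert_allclose(q, bh_oracle(p), atol=1e-12)

    def test_agrees_with_statsmodels(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(0, 1, 200)
        np.testing.assert_allclose(
            bh_adjust(p), multipletests(p, method="fdr_bh")[1], atol=1e-12
        )


class TestFoldChanges:
    def test_simple_ratio(self):
        clean = pd.DataFrame(
            {"a": [200.0, 200.0, 100.0, 100.0]}, index=["w1", "w2", "w3", "w4"]
        )
        groups = pd.Series(["case", "case", "control", "control"], index=clean.index)
        fc = fold_changes(clean, groups)
        assert fc.loc["a", "log2FC"] == pytest.approx(1.0)
        assert fc.loc["a", "FC"] == pytest.approx(2.0)

    def test_fc_is_two_to_the_log2fc(self):
        rng = np.random.default_rng(7)
        clean = pd.DataFrame(rng.lognormal(4, 1, size=(20, 25)))
        groups = pd.Series(["case"] * 10 + ["control"] * 10, index=clean.index)
        fc = fold_changes(clean, groups)
        np.testing.assert_allclose(fc["FC"], 2.0 ** fc["log2FC"], rtol=1e-12)

    def test_constant_analyte_flagged_na(self):
        clean = pd.DataFrame({"a": [0.0, 0.0, 0.0, 0.0], "b": [1, 2, 3, 4.0]})
        groups = pd.Series(["case", "case", "control", "control"], index=clean.index)
        fc = fold_changes(clean, groups)
        assert bool(fc.loc["a", "fc_undefined"]) and np.isnan(fc.loc["a", "FC"])


class TestCohortTableStats:
    def test_chi_square_without_correction_on_printed_tables(self):
        # 3/27 vs 5/25, 4/26 vs 6/24, 1/29 vs 3/27 (yes/no by group)
        assert round(chisq_2x2([[3, 27], [5, 25]])[1], 2) == 0.45
        assert round(chisq_2x2([[4, 26], [6, 24]])[1], 2) == 0.49
        assert round(chisq_2x2([[1, 29], [3, 27]])[1], 2) == 0.30

    def test_identical_proportions_give_zero_statistic(self):
        stat, p = chisq_2x2([[5, 25], [5, 25]])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chisq_2x2([[0, 0], [5, 25]])

    def test_identical_groups_t(self):
        t, p = unpaired_t([1.0, 2, 3, 4], [1.0, 2, 3, 4])
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_welch_equals_pooled_for_equal_variance_and_n(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0, 1, 20)
        b = rng.normal(0.4, 1, 20)
        b = (b - b.mean()) / b.std(ddof=1) * a.std(ddof=1) + 0.4  # match var
        tw, pw = unpaired_t(a, b, equal_var=False)
        tp, pp = unpaired_t(a, b, equal_var=True)
        assert tw == pytest.approx(tp, rel=1e-12)
        assert pw == pytest.approx(pp, rel=1e-9)

    def test_welch_matches_textbook_oracle(self):
        rng = np.random.default_rng(9)
        a = rng.normal(0, 1.5, 17)
        b = rng.normal(0.5, 0.7, 23)
        t, p = unpaired_t(a, b)
        t_o, p_o = welch_t_oracle(a, b)
        assert t == pytest.approx(t_o, abs=1e-10)
        assert p == pytest.approx(p_o, abs=1e-10)

    def test_summary_input_matches_raw_input(self):
        rng = np.random.default_rng(10)
        a, b = rng.normal(0, 1, 12), rng.normal(1, 2, 15)
        raw = unpaired_t(a, b)
        summ = unpaired_t(summary=(
            (a.mean(), a.std(ddof=1), 12), (b.mean(), b.std(ddof=1), 15)
        ))
        assert raw == pytest.approx(summ, rel=1e-12)

    def test_degenerate_zero_variance(self):
        assert unpaired_t([2.0, 2, 2], [2.0, 2, 2]) == (0.0, 1.0)
        with pytest.raises(ValueError):
            unpaired_t([2.0, 2, 2], [3.0, 3, 3])


class TestDifferentialTable:
    def test_sorted_rows_and_invariants(self, study_dataset):
        from autoreact.preprocess import preprocess_pipeline
        _, clean, normalized = preprocess_pipeline(study_dataset)
        groups = study_dataset.groups()
        diff = differential_table(
            normalized.values, clean.values, groups, study_dataset.analyte_meta
        )
        p = diff["p_value"].to_numpy()
        assert (np.diff(p) >= 0).all()
        assert (diff["adj_p_value"] >= diff["p_value"] - 1e-15).all()
        np.testing.assert_allclose(diff["FC"], 2.0 ** diff["log2FC"], rtol=1e-12)
        assert diff.shape[0] == clean.values.shape[1]

    def test_spiked_analytes_enriched_at_top(self, study_dataset):
        from autoreact.preprocess import preprocess_pipeline
        _, clean, normalized = preprocess_pipeline(study_dataset)
        diff = differential_table(
            normalized.values, clean.values, study_dataset.groups(),
            study_dataset.analyte_meta,
        )
        top10 = set(diff.index[:10])
        assert len(top10 & set(study_dataset.truth)) >= 4
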