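"""DMR statistics: normalization, EB shrinkage, tests, thresholds, FDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from medipseq.dmr import (
    DifferentialMethylation,
    call_dmrs,
    derive_delta_threshold,
    fit_empirical_bayes,
    mixture_model_fdr,
    moderated_tests,
    quantile_normalize,
    variability_filter,
)
from tests.conftest import make_feature_matrix


class TestQuantileNormalize:
    def test_hand_oracle_three_rows(self):
        fm = make_feature_matrix(np.array([[0.1, 0.6], [0.5, 0.2], [0.9, 0.4]]))
        out, flagged = quantile_normalize(fm)
        np.testing.assert_allclose(out.values["s0"], [0.15, 0.45, 0.75])
        np.testing.assert_allclose(out.values["s1"], [0.75, 0.15, 0.45])
        assert len(flagged) == 0

    def test_identical_columns_fixed_point(self):
        col = np.array([0.2, 0.5, 0.8, 0.3])
        fm = make_feature_matrix(np.column_stack([col, col, col]))
        out, _ = quantile_normalize(fm)
        np.testing.assert_allclose(out.values.to_numpy(), fm.values.to_numpy())

    def test_sorted_columns_identical_on_random_input(self):
        rng = np.random.default_rng(8)
        fm = make_feature_matrix(rng.random((60, 7)))
        out, _ = quantile_normalize(fm)
        arr = np.sort(out.values.to_numpy(), axis=0)
        for j in range(1, arr.shape[1]):
            np.testing.assert_allclose(arr[:, j], arr[:, 0], atol=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_rank_preservation_property(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.random((20, 4))
        fm = make_feature_matrix(X)
        out, _ = quantile_normalize(fm)
        for j, col in enumerate(out.values.columns):
            orig = stats.rankdata(X[:, j])
            new = stats.rankdata(out.values[col])
            np.testing.assert_allclose(orig, new)

    def test_missing_rows_passed_through_flagged(self):
        X = np.array([[0.1, 0.6], [np.nan, 0.2], [0.9, 0.4], [0.5, 0.3]])
        fm = make_feature_matrix(X)
        out, flagged = quantile_normalize(fm)
        assert list(flagged) == ["f1"]
        assert np.isnan(out.values.loc["f1", "s0"])
        assert out.values.loc["f1", "s1"] == 0.2  # unnormalized pass-through

    def test_single_column_rejected(self):
        fm = make_feature_matrix(np.array([[0.1], [0.5]]))
        with pytest.raises(ValueError):
            quantile_normalize(fm)


class TestVariabilityFilter:
    def test_constant_feature_removed(self):
        X = np.vstack([np.full(6, 0.5), np.linspace(0.1, 0.9, 6), np.linspace(0.2, 0.7, 6)])
        fm = make_feature_matrix(X)
        out, rep = variability_filter(fm)
        assert "f0" in rep.removed
        assert "f0" not in out.values.index

    def test_all_constant_class_removes_nothing(self):
        fm = make_feature_matrix(np.full((4, 5), 0.3))
        out, rep = variability_filter(fm)
        assert rep.n_removed == 0  # range 0 < threshold 0 is false
        assert len(out.values) == 4

    def test_matches_bruteforce_on_random_matrix(self):
        rng = np.random.default_rng(9)
        X = rng.random((100, 8))
        fm = make_feature_matrix(X)
        out, rep = variability_filter(fm)
        thr = np.mean(np.std(X, axis=1, ddof=1))
        expected = {f"f{i}" for i in range(100) if np.ptp(X[i]) >= thr}
        assert set(out.values.index) == expected


class TestEmpiricalBayes:
    GROUPS8 = {f"s{i}": ("A" if i < 4 else "B") for i in range(8)}

    def test_zero_prior_df_recovers_ordinary_t(self):
        rng = np.random.default_rng(10)
        X = rng.random((30, 8))
        fm = make_feature_matrix(X)
        eb = fit_empirical_bayes(fm, self.GROUPS8, force_d0=0.0)
        out = moderated_tests(fm, self.GROUPS8, eb, ("A", "B"))
        for i in range(30):
            t_ref, p_ref = stats.ttest_ind(X[i, :4], X[i, 4:])
            assert out.statistic.iloc[i] == pytest.approx(t_ref, rel=1e-9)
            assert out.p.iloc[i] == pytest.approx(p_ref, rel=1e-9)

    def test_equal_variances_degenerate_moments(self):
        # all residual variances equal -> infinite prior df, full shrinkage
        rng = np.random.default_rng(11)
        base = rng.random((20, 1))
        noise = np.tile([-1.5, -0.5, 0.5, 1.5, -1.5, -0.5, 0.5, 1.5], (20, 1)) * 0.01
        X = np.clip(base + noise, 0, 1)
        fm = make_feature_matrix(X)
        eb = fit_empirical_bayes(fm, self.GROUPS8)
        assert np.isinf(eb.d0)
        np.testing.assert_allclose(eb.s2_shrunk, eb.s02, rtol=1e-9)

    def test_hyperparameter_recovery_scaled_inv_chi2(self):
        # variances from d0=4, s0^2=0.01: the moment estimator must recover
        # them (this is the model the shrinkage assumes)
        rng = np.random.default_rng(7)
        d0, s02, dg, nfeat = 4.0, 0.01, 6.0, 5000
        true_var = d0 * s02 / rng.chisquare(d0, nfeat)
        s2 = true_var * rng.chisquare(dg, nfeat) / dg
        # build a matrix with exactly these pooled variances: two groups of 4,
        # residuals scaled to hit s2
        X = rng.standard_normal((nfeat, 8))
        for g in (slice(0, 4), slice(4, 8)):
            X[:, g] -= X[:, g].mean(axis=1, keepdims=True)
        scale = np.sqrt(s2 * dg / (X**2).sum(axis=1))
        X = X * scale[:, None] + 0.5
        fm = make_feature_matrix(np.clip(X, 0, 1))
        eb = fit_empirical_bayes(fm, self.GROUPS8)
        assert 2.5 <= eb.d0 <= 6.0
        assert abs(eb.s02 - s02) / s02 < 0.25

    def test_statistic_matches_bruteforce_shrinkage_formula(self):
        rng = np.random.default_rng(12)
        # heterogeneous per-feature noise scales keep the prior df finite
        scales = rng.lognormal(-3.0, 1.0, size=20)
        X = np.clip(0.5 + rng.standard_normal((20, 7)) * scales[:, None], 0, 1)
        groups = {f"s{i}": ("A" if i < 3 else "B") for i in range(7)}
        fm = make_feature_matrix(X, samples=list(groups))
        eb = fit_empirical_bayes(fm, groups)
        out = moderated_tests(fm, groups, eb, ("A", "B"))
        for i in range(20):
            a, b = X[i, :3], X[i, 3:]
            s2 = (np.sum((a - a.mean()) ** 2) + np.sum((b - b.mean()) ** 2)) / 5
            s2_sh = (eb.d0 * eb.s02 + 5 * s2) / (eb.d0 + 5)
            t = (a.mean() - b.mean()) / np.sqrt(s2_sh * (1 / 3 + 1 / 4))
            p = 2 * stats.t.sf(abs(t), eb.d0 + 5)
            assert out.statistic.iloc[i] == pytest.approx(t, rel=1e-9)
            assert out.p.iloc[i] == pytest.approx(p, rel=1e-9)

    def test_equal_means_give_zero_t_unit_p(self):
        # both groups see the same four values -> equal means, nonzero variance
        rng = np.random.default_rng(15)
        half = rng.random((5, 4))
        X = np.hstack([half, half])
        fm = make_feature_matrix(X)
        groups = {f"s{i}": ("A" if i < 4 else "B") for i in range(8)}
        eb = fit_empirical_bayes(fm, groups)
        out = moderated_tests(fm, groups, eb, ("A", "B"))
        np.testing.assert_allclose(out.statistic, 0.0, atol=1e-12)
        np.testing.assert_allclose(out.p, 1.0)

    def test_five_group_contrast_set(self, truth_matrix, truth):
        groups = truth.group_labels
        fm = truth_matrix.complete()
        eb = fit_empirical_bayes(fm, groups)
        vectors = {}
        for g in ("t(8;21)", "t(15;17)", "NK", "+8", "NBM"):
            vectors[g] = moderated_tests(fm, groups, eb, (g, "rest"))["p"]
        vectors["AML_vs_NBM"] = moderated_tests(fm, groups, eb, ("rest", "NBM"))["p"]
        assert len(vectors) == 6
        for v in vectors.values():
            assert ((v > 0) & (v <= 1)).all()

    def test_small_group_rejected(self):
        fm = make_feature_matrix(np.random.default_rng(0).random((10, 5)))
        groups = {"s0": "A", "s1": "B", "s2": "B", "s3": "B", "s4": "B"}
        with pytest.raises(ValueError):
            fit_empirical_bayes(fm, groups)

    def test_omnibus_f_positive_with_valid_p(self):
        rng = np.random.default_rng(13)
        X = rng.random((25, 10))
        groups = {f"s{i}": f"G{i // 2}" for i in range(10)}
        fm = make_feature_matrix(X, samples=list(groups))
        eb = fit_empirical_bayes(fm, groups)
        out = moderated_tests(fm, groups, eb, "omnibus")
        assert (out.statistic >= 0).all()
        assert ((out.p > 0) & (out.p <= 1)).all()


class TestDeltaThreshold:
    def test_constant_input(self):
        t = derive_delta_threshold(np.full(150, 0.2))
        assert t.raw == pytest.approx(0.2)
        assert t.rounded == pytest.approx(0.2)

    def test_exact_grid_percentile(self):
        t = derive_delta_threshold(np.round(np.linspace(0, 1, 101), 2))
        assert t.raw == pytest.approx(0.99)

    def test_published_rounding_instance(self):
        t = derive_delta_threshold(np.full(200, 0.23))
        assert t.rounded == pytest.approx(0.25)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            derive_delta_threshold([])


class TestCallDmrs:
    def _tests_frame(self, rows):
        idx = pd.Index([f"f{i}" for i in range(len(rows))], name="feature_id")
        return pd.DataFrame(rows, columns=["p", "delta"], index=idx)

    def test_rule_is_strict_on_both_conditions(self):
        out = call_dmrs(self._tests_frame([(0.03, 0.30), (0.03, 0.20), (0.06, 0.40),
                                           (0.03, 0.25), (0.05, 0.30)]))
        assert out.is_dmr.tolist() == [True, False, False, False, False]
        assert out.direction.tolist() == ["hyper", "", "", "", ""]

    def test_hypo_direction(self):
        out = call_dmrs(self._tests_frame([(0.01, -0.4)]))
        assert out.direction.tolist() == ["hypo"]

    def test_bh_monotone_in_raw_p(self):
        rng = np.random.default_rng(14)
        out = call_dmrs(self._tests_frame(list(zip(rng.random(200), rng.random(200)))))
        srt = out.sort_values("p")
        assert (np.diff(srt.p_adj) >= -1e-12).all()

    def test_mismatched_ids_rejected(self):
        t = self._tests_frame([(0.01, 0.3)])
        deltas = pd.Series([0.3], index=pd.Index(["other"], name="feature_id"))
        with pytest.raises(ValueError):
            call_dmrs(t.drop(columns="delta"), deltas)


class TestMixtureFdr:
    def test_pure_null_lambda_near_one(self):
        rng = np.random.default_rng(3)
        p = rng.random(5000)
        fit = mixture_model_fdr(np.clip(p, 1e-9, 1.0))
        assert fit.lambda_ >= 0.9
        assert fit.fdr_at_threshold >= 0.8

    def test_labeled_signal_fdr_within_band(self):
        rng = np.random.default_rng(3)
        n_sig, n_null = 1500, 3500
        p_sig = rng.beta(0.1, 1.0, n_sig)
        p_null = rng.random(n_null)
        p = np.clip(np.concatenate([p_sig, p_null]), 1e-12, 1.0)
        fit = mixture_model_fdr(p, p_thresh=0.05)
        realized = (p_null <= 0.05).sum() / max((p <= 0.05).sum(), 1)
        assert abs(fit.fdr_at_threshold - realized) <= 0.05

    def test_degenerate_all_ones_flagged(self):
        fit = mixture_model_fdr(np.ones(300))
        assert fit.lambda_ > 0.95
        assert fit.boundary

    def test_too_few_pvalues_rejected(self):
        with pytest.raises(ValueError):
            mixture_model_fdr(np.random.default_rng(0).random(100))


class TestModelWrapper:
    def test_summary_and_tables(self, truth_matrix, truth):
        model = DifferentialMethylation(truth_matrix, truth.group_labels)
        res = model.fit(("rest", "NBM"))
        text = res.summary()
        assert "Differential methylation" in text
        assert "DMR rule" in text
        assert res.dmrs.is_dmr.all()
        assert set(res.table.columns) >= {"delta", "statistic", "p", "p_adj", "is_dmr", "direction"}

    def test_derived_threshold_path(self, truth_matrix, truth):
        model = DifferentialMethylation(truth_matrix, truth.group_labels)
        res = model.fit(("rest", "NBM"), delta_thresh=None)
        assert res.threshold is not None
        assert res.delta_thresh == res.threshold.rounded
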