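"""Classifier oracles: closed forms, enumeration, and cross-method contracts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from polydev import (
    CallSet,
    MahalanobisModel,
    RankNullStore,
    classify_centile,
    classify_grs_rank,
    classify_mahalanobis,
    classify_residual,
    centile_fences,
    fit_mahalanobis,
    mahalanobis_pvalues,
    method_overlap,
    residual_z,
    split_direction,
)
from polydev.errors import ConfigError, DataError

from conftest import bivariate_pairs, raw_pairs


class TestMahalanobisModel:
    def test_perfectly_correlated_pairs_rejected(self):
        x = np.linspace(-2, 2, 50)
        with pytest.raises(DataError, match="correlation"):
            fit_mahalanobis(raw_pairs(range(50), x, x))

    def test_covariance_offdiag_equals_sqrt_r2(self):
        # corr(ps, pheno) = sqrt(variance explained)
        pairs = bivariate_pairs(50_000, np.sqrt(0.25), seed=1)
        model = fit_mahalanobis(pairs)
        assert abs(model.covariance[0, 1] - 0.5) < 0.02
        np.testing.assert_allclose(np.diag(model.covariance), 1.0, atol=1e-10)

    def test_independent_components_identity_covariance(self):
        pairs = bivariate_pairs(50_000, 0.0, seed=2)
        model = fit_mahalanobis(pairs)
        np.testing.assert_allclose(model.covariance, np.eye(2), atol=0.02)


class TestMahalanobisPvalues:
    def test_center_point(self):
        model = MahalanobisModel(center=np.zeros(2), covariance=np.eye(2))
        d2, p = mahalanobis_pvalues(raw_pairs(["a"], [0.0], [0.0]), model)
        assert d2[0] == pytest.approx(0.0, abs=1e-14)
        assert p[0] == pytest.approx(1.0, abs=1e-14)

    def test_identity_covariance_closed_form(self):
        model = MahalanobisModel(center=np.zeros(2), covariance=np.eye(2))
        d2, p = mahalanobis_pvalues(raw_pairs(["a"], [2.0], [0.0]), model)
        assert d2[0] == pytest.approx(4.0, abs=1e-12)
        assert p[0] == pytest.approx(np.exp(-2.0), abs=1e-12)

    def test_correlated_covariance_matrix_inverse_oracle(self):
        S = np.array([[1.0, 0.5], [0.5, 1.0]])
        model = MahalanobisModel(center=np.zeros(2), covariance=S)
        x = np.array([1.0, -1.0])
        d2, p = mahalanobis_pvalues(raw_pairs(["a"], [x[0]], [x[1]]), model)
        # brute-force 2x2 inverse
        det = S[0, 0] * S[1, 1] - S[0, 1] * S[1, 0]
        Sinv = np.array([[S[1, 1], -S[0, 1]], [-S[1, 0], S[0, 0]]]) / det
        assert d2[0] == pytest.approx(x @ Sinv @ x, abs=1e-12)
        assert d2[0] == pytest.approx(4.0, abs=1e-12)
        assert p[0] == pytest.approx(np.exp(-2.0), abs=1e-12)

    def test_chi2_tail_equals_exponential_closed_form(self):
        d2 = np.linspace(0, 50, 501)
        np.testing.assert_allclose(stats.chi2.sf(d2, 2), np.exp(-d2 / 2), atol=1e-12)

    def test_nonfinite_pair_named(self):
        model = MahalanobisModel(center=np.zeros(2), covariance=np.eye(2))
        with pytest.raises(DataError, match="bad_ind"):
            mahalanobis_pvalues(raw_pairs(["ok", "bad_ind"], [0, np.nan], [0, 0]), model)


class TestClassifyMahalanobis:
    def test_alpha_range_checked(self, null_pairs):
        model = fit_mahalanobis(null_pairs)
        with pytest.raises(ConfigError):
            classify_mahalanobis(null_pairs, model, alpha=1.5)

    def test_cohort_hugging_center_has_no_deviators(self):
        pairs = bivariate_pairs(2_000, 0.0, seed=3)
        model = fit_mahalanobis(bivariate_pairs(20_000, 0.562, seed=4))
        tight = raw_pairs(
            pairs["individual_id"], pairs["ps_z"] * 0.1, pairs["pheno_z"] * 0.1
        )
        calls = classify_mahalanobis(tight, model)
        assert calls.deviators == set()
        assert set(calls.table["status"]) <= {"aligned", "intermediate"}

    def test_deviators_satisfy_joint_residual_rule(self, null_pairs):
        model = fit_mahalanobis(bivariate_pairs(20_000, 0.562, seed=5))
        calls = classify_mahalanobis(null_pairs, model, alpha=0.01, z_dev=2.0)
        z = residual_z(null_pairs)
        flagged = calls.table["status"].str.startswith("deviator").to_numpy()
        assert (np.abs(z[flagged]) > 2).all()

    def test_bonferroni_callset_nested_in_lenient(self, null_pairs):
        model = fit_mahalanobis(bivariate_pairs(20_000, 0.562, seed=5))
        lenient = classify_mahalanobis(null_pairs, model, alpha=1e-3)
        strict = classify_mahalanobis(
            null_pairs, model, alpha=0.05 / len(null_pairs), threshold_label="P<0.05/n"
        )
        assert strict.threshold_label == "P<0.05/n"
        assert strict.deviators <= lenient.deviators


class TestClassifyResidual:
    def test_degenerate_pairs_rejected(self):
        x = np.linspace(-2, 2, 100)
        with pytest.raises(DataError, match="residual"):
            classify_residual(raw_pairs(range(100), x, x))

    def test_null_flag_rate_near_two_sided_normal_tail(self):
        pairs = bivariate_pairs(50_000, 0.562, seed=6)
        calls = classify_residual(pairs, k=2.0)
        frac = len(calls.deviators) / len(pairs)
        assert abs(frac - 2 * stats.norm.sf(2)) < 0.007

    def test_k3_nested_in_k2(self, null_pairs):
        assert (
            classify_residual(null_pairs, k=3.0).deviators
            <= classify_residual(null_pairs, k=2.0).deviators
        )

    def test_direction_matches_phenotype_sign(self, null_pairs):
        calls = classify_residual(null_pairs, k=2.0)
        merged = calls.table.merge(null_pairs, on="individual_id")
        low = merged["status"] == "deviator_low"
        high = merged["status"] == "deviator_high"
        assert (merged.loc[low, "pheno_z"] < 0).all()
        assert (merged.loc[high, "pheno_z"] > 0).all()


def _toy_store():
    # n=5 ranks, B=4 replicates; hand-enumerable
    values = np.array(
        [
            [-1.0, -0.5, 0.0, 0.5, 1.0],
            [-2.0, 0.5, 0.2, 0.1, 2.0],
            [-0.5, -1.5, -0.2, 0.9, 0.8],
            [-1.2, 0.0, 0.4, 1.5, 1.2],
        ]
    )
    return RankNullStore(n=5, B=4, values=values)


class TestClassifyGrsRank:
    def test_toy_store_matches_exhaustive_enumeration(self):
        store = _toy_store()
        ps = np.array([0.1, -1.3, 2.0, 0.5, -0.4])  # ranks: 2,0,4,3,1
        y = np.array([0.05, -3.0, 1.4, 0.0, -0.1])
        pairs = raw_pairs([f"i{k}" for k in range(5)], ps, y)
        calls = classify_grs_rank(pairs, store, alpha=0.26)
        ranks = np.argsort(np.argsort(ps))
        med = np.median(store.values, axis=0)
        for i in range(5):
            k = ranks[i]
            e = abs(y[i] - med[k])
            r = sum(abs(store.values[b, k] - med[k]) >= e for b in range(4))
            expected = (r + 1) / 5
            assert calls.table["p"].iloc[i] == pytest.approx(expected, abs=1e-12)

    def test_minimum_p_is_one_over_b_plus_one(self):
        store = _toy_store()
        ps = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        y = np.array([-9.0, 0.0, 0.0, 0.0, 9.0])  # extremes beat every replicate
        calls = classify_grs_rank(raw_pairs(range(5), ps, y), store, alpha=0.5)
        assert calls.table["p"].min() == pytest.approx(1 / 5, abs=1e-15)
        assert set(calls.table["p"]) <= {(r + 1) / 5 for r in range(5)}

    def test_maximal_r_gives_p_one(self):
        store = _toy_store()
        med = np.median(store.values, axis=0)
        ps = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        calls = classify_grs_rank(raw_pairs(range(5), ps, med), store, alpha=0.5)
        assert (calls.table["p"] == 1.0).all()

    def test_p_monotone_nonincreasing_in_extremity(self):
        cfg_pairs = bivariate_pairs(300, 0.5, seed=8)
        # identical null values at every rank, so p depends only on extremity
        values = np.tile(np.random.default_rng(9).standard_normal((50, 1)), (1, 300))
        store = RankNullStore(n=300, B=50, values=values)
        calls = classify_grs_rank(cfg_pairs, store, alpha=0.05)
        df = calls.table.sort_values("statistic")
        assert (np.diff(df["p"].to_numpy()) <= 1e-12).all()

    def test_cohort_size_mismatch_rejected(self):
        with pytest.raises(DataError, match="n="):
            classify_grs_rank(bivariate_pairs(10, 0.5, seed=1), _toy_store())


class TestClassifyCentile:
    def test_single_bin_quartile_fence_oracle(self):
        y = np.array([1.0, 2, 3, 4, 5, 6, 7, 8, 100.0])
        pairs = raw_pairs(range(9), np.arange(9.0), y)
        calls = classify_centile(pairs, k_iqr=1.5, bins=1)
        q1, q3 = np.percentile(y, [25, 75])
        fences = centile_fences(pairs, k_iqr=1.5, bins=1)
        assert fences["q1"].iloc[0] == pytest.approx(q1)
        assert fences["upper"].iloc[0] == pytest.approx(q3 + 1.5 * (q3 - q1))
        flagged = calls.table.loc[
            calls.table["status"].str.startswith("deviator"), "individual_id"
        ]
        assert set(flagged) == {8}  # only the value 100 is outside the fences

    def test_constant_phenotype_within_bins_flags_nobody(self):
        # zero IQR, nothing exceeds the collapsed fences
        ps = np.arange(40.0)
        y = np.repeat([0.0, 1.0], 20)[np.argsort(np.argsort(ps))]
        calls = classify_centile(raw_pairs(range(40), ps, y), k_iqr=1.5, bins=2)
        assert calls.deviators == set()

    def test_k3_nested_in_k15(self, null_pairs):
        assert (
            classify_centile(null_pairs, k_iqr=3.0).deviators
            <= classify_centile(null_pairs, k_iqr=1.5).deviators
        )

    def test_bins_validated(self, null_pairs):
        with pytest.raises(ConfigError):
            classify_centile(null_pairs, bins=0)


class TestDirectionAndOverlap:
    def _calls_with_deviator(self, ids, ps, y, dev_ids):
        pairs = raw_pairs(ids, ps, y)
        status = np.where(np.isin(np.asarray(ids, dtype=object), dev_ids), "deviator_low", "aligned")
        table = pd.DataFrame(
            {"individual_id": np.asarray(ids, dtype=object), "status": status,
             "statistic": 0.0, "p": np.nan}
        )
        return CallSet("residual", "test", table), pairs

    def test_negative_phenotype_deviator_is_low(self):
        rng = np.random.default_rng(10)
        ids = [f"i{k}" for k in range(50)]
        ps, y = rng.standard_normal(50), rng.standard_normal(50)
        y[0] = -2.5
        calls, pairs = self._calls_with_deviator(ids, ps, y, ["i0"])
        out = split_direction(calls, pairs, rule="phenotype")
        assert out.table.loc[out.table["individual_id"] == "i0", "status"].item() == "deviator_low"

    def test_phenotype_vs_residual_rule_disagree_on_constructed_point(self):
        # slightly-below-mean phenotype with a strongly positive residual:
        # the phenotype rule calls it low, the residual rule high
        rng = np.random.default_rng(11)
        ids = [f"i{k}" for k in range(100)]
        ps = rng.standard_normal(100)
        y = 0.6 * ps + 0.3 * rng.standard_normal(100)
        ps[0], y[0] = -4.0, -0.1  # far above the line through (-4, -2.4)
        calls, pairs = self._calls_with_deviator(ids, ps, y, ["i0"])
        pheno_rule = split_direction(calls, pairs, rule="phenotype")
        resid_rule = split_direction(calls, pairs, rule="residual")
        get = lambda cs: cs.table.loc[cs.table["individual_id"] == "i0", "status"].item()
        assert get(pheno_rule) == "deviator_low"
        assert get(resid_rule) == "deviator_high"

    def test_no_deviators_is_noop(self):
        rng = np.random.default_rng(12)
        ids = [f"i{k}" for k in range(20)]
        calls, pairs = self._calls_with_deviator(
            ids, rng.standard_normal(20), rng.standard_normal(20), []
        )
        out = split_direction(calls, pairs)
        assert out.table["status"].equals(calls.table["status"])

    def _callset(self, n, low_ids, method="m", label="t"):
        ids = [f"i{k}" for k in range(n)]
        status = np.where(np.isin(ids, low_ids), "deviator_low", "aligned")
        return CallSet(
            method, label,
            pd.DataFrame({"individual_id": np.asarray(ids, dtype=object),
                          "status": status, "statistic": 0.0, "p": np.nan}),
        )

    def test_overlap_identity_and_disjoint(self):
        a = self._callset(10, ["i1", "i2"], "a")
        b = self._callset(10, ["i3", "i4"], "b")
        ov = method_overlap([a, b]).set_index(["direction", "method_a", "method_b"])
        assert ov.loc[("deviator_low", "a:t", "a:t"), "pct"] == 100.0
        assert ov.loc[("deviator_low", "a:t", "b:t"), "pct"] == 0.0

    def test_overlap_asymmetric_counts(self):
        a = self._callset(10, ["i1", "i2", "i3", "i4"], "a")
        b = self._callset(10, ["i3", "i4"], "b")
        ov = method_overlap([a, b]).set_index(["direction", "method_a", "method_b"])
        assert ov.loc[("deviator_low", "a:t", "b:t"), "pct"] == 50.0
        assert ov.loc[("deviator_low", "b:t", "a:t"), "pct"] == 100.0

    def test_mismatched_cohorts_rejected(self):
        with pytest.raises(DataError, match="cohort"):
            method_overlap([self._callset(10, []), self._callset(11, [])])


class TestRowOrderInvariance:
    def test_all_classifiers_invariant_to_permutation(self, null_pairs):
        perm = np.random.default_rng(13).permutation(len(null_pairs))
        shuffled = null_pairs.iloc[perm].reset_index(drop=True)
        model = fit_mahalanobis(bivariate_pairs(20_000, 0.562, seed=5))
        store = RankNullStore(
            n=len(null_pairs),
            B=20,
            values=np.random.default_rng(14).standard_normal((20, len(null_pairs))),
        )
        for fn in (
            lambda p: classify_mahalanobis(p, model, alpha=0.01),
            lambda p: classify_residual(p, k=2.0),
            lambda p: classify_grs_rank(p, store, alpha=0.05),
            lambda p: classify_centile(p, k_iqr=1.5),
        ):
            base = fn(null_pairs).table.set_index("individual_id")["status"]
            after = fn(shuffled).table.set_index("individual_id")["status"]
            assert base.sort_index().equals(after.sort_index())
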