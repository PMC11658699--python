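"""Federated DGE/EWAS: preprocessing, per-feature models, meta combination."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from fedomics import (
    FeatureMatrix,
    PhenotypeTable,
    create_session,
    simulate_feature_matrix,
)
from fedomics.omics import (
    DesignSpec,
    federated_filter_low_counts,
    filter_low_counts,
    log_cpm,
    meta_features,
    mvalues,
    per_feature_lm,
    pooled_feature_lm,
    winsorize,
)
from tests.conftest import OPEN


def counts_matrix(values, prefix="s"):
    values = np.asarray(values, dtype=float)
    feats = pd.DataFrame(
        {"feature_id": [f"f{i + 1}" for i in range(values.shape[0])]}
    )
    return FeatureMatrix(
        values, feats, [f"{prefix}{j}" for j in range(values.shape[1])], "counts"
    )


def feature_session(mats, groups, config=OPEN, seed=0):
    site_data = []
    for m, g in zip(mats, groups):
        ph = PhenotypeTable(list(m.sample_ids), np.asarray(g, dtype=float))
        site_data.append((None, ph, m, config))
    return create_session(site_data, seed=seed)


class TestLowCountFilter:
    def test_hand_computed_cpm_keep_set(self):
        # library sizes 100 and 200 => CPM = count/libsize * 1e6
        vals = np.array(
            [
                [90, 180],  # CPM 9e5 both: kept
                [0, 0],  # all-zero: dropped
                [10, 0],  # CPM (1e5, 0): kept in 50% of samples only
                [0, 20],
            ]
        )
        m = counts_matrix(vals)
        kept = filter_low_counts(m, min_cpm=1.0, min_sample_fraction=0.75)
        assert kept == ["f1"]
        kept_half = filter_low_counts(m, min_cpm=1.0, min_sample_fraction=0.5)
        assert kept_half == ["f1", "f3", "f4"]

    def test_zero_min_cpm_keeps_everything_expressed(self):
        vals = np.array([[1, 1], [5, 5]])
        m = counts_matrix(vals)
        assert filter_low_counts(m, min_cpm=0.0, min_sample_fraction=1.0) == [
            "f1",
            "f2",
        ]

    def test_all_zero_feature_dropped(self):
        m = counts_matrix(np.array([[0, 0], [3, 3]]))
        assert "f1" not in filter_low_counts(m, min_cpm=0.5)

    def test_zero_library_size_rejected(self):
        m = counts_matrix(np.array([[0, 5], [0, 5]]))
        with pytest.raises(ValueError, match="library size"):
            filter_low_counts(m)

    def test_federated_filter_intersects_sites(self):
        a = counts_matrix(np.array([[100, 100], [100, 100], [0, 0]]), "a")
        b = counts_matrix(np.array([[100, 100], [0, 0], [100, 100]]), "b")
        sess = feature_session([a, b], [[0, 1], [0, 1]])
        assert federated_filter_low_counts(sess, min_cpm=1.0) == ["f1"]


class TestWinsorize:
    def test_zero_tail_is_identity(self):
        m = counts_matrix(np.arange(12).reshape(2, 6))
        out = winsorize(m, 0.0)
        np.testing.assert_array_equal(out.values, m.values)

    def test_clamps_to_empirical_quantiles(self):
        v = np.arange(1.0, 101.0)[None, :]
        feats = pd.DataFrame({"feature_id": ["f1"]})
        m = FeatureMatrix(v, feats, [f"s{i}" for i in range(100)], "continuous")
        out = winsorize(m, 0.05)
        lo = np.quantile(v, 0.05)
        hi = np.quantile(v, 0.95)
        assert out.values.min() == pytest.approx(lo)
        assert out.values.max() == pytest.approx(hi)

    def test_rank_order_preserved_among_unclamped(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=(1, 50))
        feats = pd.DataFrame({"feature_id": ["f1"]})
        m = FeatureMatrix(v, feats, [f"s{i}" for i in range(50)], "continuous")
        out = winsorize(m, 0.1)
        inner = (v[0] > np.quantile(v, 0.1)) & (v[0] < np.quantile(v, 0.9))
        assert np.array_equal(
            np.argsort(v[0][inner]), np.argsort(out.values[0][inner])
        )

    def test_median_unchanged(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=(3, 41))
        feats = pd.DataFrame({"feature_id": ["f1", "f2", "f3"]})
        m = FeatureMatrix(v, feats, [f"s{i}" for i in range(41)], "continuous")
        out = winsorize(m, 0.2)
        np.testing.assert_allclose(
            np.median(out.values, axis=1), np.median(v, axis=1)
        )


class TestTransforms:
    def test_mvalue_half_beta_is_zero(self):
        assert mvalues(np.array([0.5]))[0] == pytest.approx(0.0)

    def test_log_cpm_monotone_in_counts(self):
        v = np.array([[1.0, 1.0], [10.0, 10.0], [100.0, 100.0]])
        out = log_cpm(v)
        assert np.all(np.diff(out[:, 0]) > 0)


class TestPerFeatureLm:
    @pytest.fixture
    def small_study(self):
        mats, groups, de = simulate_feature_matrix(
            20, [24], de_fraction=0.25, log2_fold_change=2.0, seed=5
        )
        sess = feature_session(mats, [g.outcome for g in groups])
        return sess, mats[0], groups[0].outcome

    def test_matches_per_feature_ols_oracle(self, small_study):
        sess, mat, group = small_study
        tables = per_feature_lm(sess, DesignSpec("outcome"), transform="log_cpm")
        Y = log_cpm(mat.values)
        X = np.column_stack([np.ones(len(group)), group])
        for j in range(20):
            fit = sm.OLS(Y[j], X).fit()
            assert tables[0].loc[j, "effect"] == pytest.approx(
                fit.params[1], abs=1e-8
            )
            assert tables[0].loc[j, "se"] == pytest.approx(fit.bse[1], abs=1e-8)
            assert tables[0].loc[j, "p"] == pytest.approx(
                fit.pvalues[1], abs=1e-8
            )

    def test_balanced_identical_group_means_give_zero_effect(self):
        vals = np.tile([10.0, 20.0, 10.0, 20.0], (2, 1)) * 10
        m = counts_matrix(vals)
        sess = feature_session([m], [[0, 0, 1, 1]])
        tables = per_feature_lm(sess, DesignSpec("outcome"), transform="log_cpm")
        np.testing.assert_allclose(tables[0]["effect"], 0.0, atol=1e-12)

    def test_rank_deficient_design_rejected(self):
        m = counts_matrix(np.full((2, 4), 10.0))
        ph = PhenotypeTable(
            list(m.sample_ids),
            np.array([0.0, 0.0, 1.0, 1.0]),
            pd.DataFrame({"dup": [0.0, 0.0, 1.0, 1.0]}),
        )
        sess = create_session([(None, ph, m, OPEN)])
        with pytest.raises(ValueError, match="rank-deficient"):
            per_feature_lm(sess, DesignSpec("outcome", ("dup",)))


class TestPooledFeatureLm:
    def test_equals_concatenated_ols(self):
        mats, groups, _ = simulate_feature_matrix(
            15, [20, 30, 12], de_fraction=0.2, n_sites=3, seed=6
        )
        sess = feature_session(mats, [g.outcome for g in groups])
        pooled = pooled_feature_lm(sess, DesignSpec("outcome"), transform="log_cpm")
        Y = np.hstack([log_cpm(m.values) for m in mats])
        g = np.concatenate([g.outcome for g in groups])
        X = np.column_stack([np.ones(len(g)), g])
        coef = np.linalg.lstsq(X, Y.T, rcond=None)[0]
        np.testing.assert_allclose(
            pooled["effect"], coef[1], rtol=1e-10, atol=1e-12
        )

    def test_single_site_equals_per_site_fit(self):
        mats, groups, _ = simulate_feature_matrix(10, [26], seed=7)
        sess = feature_session(mats, [g.outcome for g in groups])
        pooled = pooled_feature_lm(sess, DesignSpec("outcome"), transform="log_cpm")
        per = per_feature_lm(sess, DesignSpec("outcome"), transform="log_cpm")[0]
        np.testing.assert_allclose(pooled["effect"], per["effect"], rtol=1e-10)
        np.testing.assert_allclose(pooled["p"], per["p"], rtol=1e-8)

    def test_all_missing_feature_excluded_from_n(self):
        a = counts_matrix(np.array([[5, 10, 5, 10], [4, 8, 4, 8]]), "a")
        vals_b = np.array([[np.nan] * 4, [6.0, 12, 6, 12]])
        feats = pd.DataFrame({"feature_id": ["f1", "f2"]})
        b = FeatureMatrix(vals_b, feats, [f"b{j}" for j in range(4)], "continuous")
        sess = feature_session([a, b], [[0, 0, 1, 1], [0, 0, 1, 1]])
        pooled = pooled_feature_lm(sess, DesignSpec("outcome"))
        assert pooled.loc[0, "n"] == 4  # site b missing f1 entirely
        assert pooled.loc[1, "n"] == 8


class TestMetaFeatures:
    def test_single_site_identity(self):
        t = pd.DataFrame(
            {"feature_id": ["f1"], "p": [0.02], "site": "a"}
        )
        out = meta_features([t])
        assert out.loc[0, "p"] == pytest.approx(0.02, rel=1e-10)

    def test_bonferroni_threshold_definition(self):
        t = pd.DataFrame(
            {"feature_id": [f"f{i}" for i in range(10)],
             "p": np.linspace(0.001, 0.5, 10), "site": "a"}
        )
        out = meta_features([t], adjust="bonferroni")
        np.testing.assert_allclose(
            out["p_adj"], np.minimum(out["p"] * 10, 1.0)
        )

    def test_null_combination_calibrated(self):
        rng = np.random.default_rng(8)
        tables = [
            pd.DataFrame(
                {"feature_id": [f"f{i}" for i in range(2000)],
                 "p": rng.random(2000), "site": s}
            )
            for s in ("a", "b", "c")
        ]
        out = meta_features(tables)
        frac = np.mean(out["p"] < 0.05)
        assert 0.035 <= frac <= 0.065

    def test_pooled_and_meta_rankings_agree(self):
        # homogeneous sites: Bonferroni-significant sets overlap strongly
        mats, groups, de = simulate_feature_matrix(
            400, [40, 40, 40], de_fraction=0.1, log2_fold_change=2.0,
            n_sites=3, seed=9,
        )
        sess = feature_session(mats, [g.outcome for g in groups])
        design = DesignSpec("outcome")
        pooled = pooled_feature_lm(sess, design, transform="log_cpm")
        pooled_sig = set(
            pooled.loc[pooled["p"] < 0.05 / len(pooled), "feature_id"]
        )
        meta = meta_features(
            per_feature_lm(sess, design, transform="log_cpm"),
            adjust="bonferroni",
        )
        meta_sig = set(meta.loc[meta["p"] < 0.05 / len(meta), "feature_id"])
        jaccard = len(pooled_sig & meta_sig) / len(pooled_sig | meta_sig)
        assert jaccard >= 0.7
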