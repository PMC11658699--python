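"""Federated GWAS operations against single-machine and closed-form oracles."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from fedomics import (
    PGSModel,
    PhenotypeTable,
    PrivacyConfig,
    allele_frequency,
    compute_prs,
    create_session,
    exact_hwe,
    fast_pooled_gwas,
    fit_null_glm,
    meta_gwas,
    per_snp_glm,
    pooled_pca,
    standardize_genotypes,
)
from fedomics.gwas import hwe_exact_pvalue
from tests.conftest import OPEN, make_block, make_session_from_dosages


class TestAlleleFrequency:
    def test_pooled_matches_direct_count(self):
        # site A [0,1,2], site B [2,2]: 7 alt alleles over 10
        sess = make_session_from_dosages([[[0, 1, 2]], [[2, 2]]])
        af = allele_frequency(sess)
        assert af.loc[0, "frequency"] == pytest.approx(0.7)
        assert af.loc[0, "maf"] == pytest.approx(0.3)

    def test_missing_genotypes_excluded_from_allele_number(self):
        sess = make_session_from_dosages([[[0, np.nan, 2]]])
        af = allele_frequency(sess)
        assert af.loc[0, "allele_number"] == 4
        assert af.loc[0, "frequency"] == pytest.approx(0.5)

    def test_monomorphic_masked_under_default_threshold(self):
        cfg = PrivacyConfig(dp_enabled=False)  # MAF threshold 0.05
        sess = make_session_from_dosages(
            [np.vstack([np.zeros(30), np.random.default_rng(0).binomial(2, 0.4, 30)])],
            config=cfg,
        )
        af = allele_frequency(sess)
        assert np.isnan(af.loc[0, "frequency"])  # masked monomorphic
        assert np.isfinite(af.loc[1, "frequency"])

    def test_per_site_mode_reports_each_site(self):
        sess = make_session_from_dosages([[[0, 1, 2]], [[2, 2]]])
        af = allele_frequency(sess, mode="per_site")
        assert set(af["site"]) == {"site1", "site2"}
        a = af[af["site"] == "site1"]["frequency"].iloc[0]
        assert a == pytest.approx(0.5)


def hwe_oracle(n_het, n_hom_minor, n_hom_major):
    """Independent exact-test oracle using rational combinatorics."""
    n = n_het + n_hom_minor + n_hom_major
    na = 2 * n_hom_minor + n_het
    nb = 2 * n_hom_major + n_het
    if na > nb:
        na, nb = nb, na
    if na == 0:
        return 1.0
    from fractions import Fraction

    denom = Fraction(math.factorial(2 * n),
                     math.factorial(na) * math.factorial(nb))
    probs = {}
    for h in range(na % 2, na + 1, 2):
        ha, hb = (na - h) // 2, (nb - h) // 2
        if hb < 0:
            continue
        num = Fraction(
            math.factorial(n) * 2**h,
            math.factorial(ha) * math.factorial(h) * math.factorial(hb),
        )
        probs[h] = num / denom
    obs = probs[n_het]
    return float(sum(p for p in probs.values() if p <= obs))


class TestExactHwe:
    def test_zero_minor_copies_gives_p_one(self):
        assert hwe_exact_pvalue(0, 0, 25) == 1.0

    def test_two_sample_enumeration(self):
        # (hom_minor=1, het=0, hom_major=1): attainable het in {0, 2};
        # P(het=0)=1/3, P(het=2)=2/3, so p = 1/3
        assert hwe_exact_pvalue(0, 1, 1) == pytest.approx(1 / 3)
        assert hwe_oracle(0, 1, 1) == pytest.approx(1 / 3)

    @pytest.mark.parametrize(
        "het,hom_min,hom_maj",
        [(0, 1, 1), (3, 2, 10), (10, 0, 5), (4, 4, 4), (7, 1, 20)],
    )
    def test_matches_rational_enumeration_oracle(self, het, hom_min, hom_maj):
        assert hwe_exact_pvalue(het, hom_min, hom_maj) == pytest.approx(
            hwe_oracle(het, hom_min, hom_maj), rel=1e-10
        )

    def test_symmetric_under_allele_label_swap(self):
        assert hwe_exact_pvalue(3, 2, 10) == hwe_exact_pvalue(3, 10, 2)

    def test_session_combination_uses_fisher(self, two_site_session):
        out = exact_hwe(two_site_session)
        assert {"p_site1", "p_site2", "p_fisher"} <= set(out.columns)
        assert np.all((out["p_fisher"] > 0) & (out["p_fisher"] <= 1))

    def test_controls_only_requires_binary_outcome(self, two_site_session):
        with pytest.raises(ValueError, match="binary"):
            exact_hwe(two_site_session, controls_only=True)


class TestNullGlm:
    def test_gaussian_intercept_only_equals_pooled_mean(self, two_site_session):
        fit = fit_null_glm(two_site_session, "outcome ~ 1")
        y = np.concatenate(
            [p.phenotypes.outcome for p in two_site_session.processors]
        )
        assert fit.coefficients[0] == pytest.approx(y.mean(), abs=1e-10)

    def test_binomial_intercept_only_equals_logit_prevalence(self):
        rng = np.random.default_rng(0)
        dosages = [rng.binomial(2, 0.3, size=(2, 40)) for _ in range(2)]
        y = [rng.binomial(1, 0.3, size=40).astype(float) for _ in range(2)]
        sess = make_session_from_dosages(dosages, phenotypes=y)
        fit = fit_null_glm(sess, "outcome ~ 1", family="binomial")
        prev = np.concatenate(y).mean()
        assert fit.coefficients[0] == pytest.approx(
            np.log(prev / (1 - prev)), abs=1e-6
        )

    def test_matches_single_machine_glm(self, two_site_session, concatenated):
        _, y, X = concatenated
        fit = fit_null_glm(two_site_session, "outcome ~ age")
        oracle = sm.GLM(y, X, family=sm.families.Gaussian()).fit()
        np.testing.assert_allclose(fit.coefficients, oracle.params, atol=1e-6)

    def test_residuals_stay_server_side(self, two_site_session):
        fit = fit_null_glm(two_site_session, "outcome ~ age")
        for proc in two_site_session.processors:
            assert "null_resid" in proc.server_side_store
            assert len(proc.server_side_store["null_resid"]) == proc.n_samples
        # the client-side fit object carries only coefficients
        assert not hasattr(fit, "residuals")


class TestFastPooledGwas:
    def test_equals_single_machine_formulas(self, two_site_session, concatenated):
        G, y, X = concatenated
        null = fit_null_glm(two_site_session, "outcome ~ age")
        fed = fast_pooled_gwas(two_site_session, null)
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        yc = (y - X @ coef) - (y - X @ coef).mean()
        n = len(y)
        B, S1, S2 = G @ yc, G.sum(1), (G**2).sum(1)
        den1 = S2 - S1**2 / n
        beta = B / den1
        sigma = (np.sum(yc**2) - beta**2 * den1) / (n - 1 - 2)
        err = np.sqrt(sigma / den1)
        ok = np.isfinite(fed["beta"])
        np.testing.assert_allclose(
            fed["beta"][ok], beta[ok.to_numpy()], rtol=1e-10
        )
        np.testing.assert_allclose(fed["se"][ok], err[ok.to_numpy()], rtol=1e-10)

    def test_intercept_only_equals_ols_slope(self):
        rng = np.random.default_rng(1)
        dosages = [rng.binomial(2, 0.4, size=(5, 50)) for _ in range(2)]
        ys = [rng.normal(size=50) for _ in range(2)]
        sess = make_session_from_dosages(dosages, phenotypes=ys)
        null = fit_null_glm(sess, "outcome ~ 1")
        fed = fast_pooled_gwas(sess, null)
        G = np.hstack(dosages).astype(float)
        y = np.concatenate(ys)
        for j in range(5):
            slope = np.polyfit(G[j], y, 1)[0]
            assert fed.loc[j, "beta"] == pytest.approx(slope, rel=1e-8)

    def test_orthogonal_variant_gives_p_one(self):
        # dosage pattern orthogonal to the centred residuals => B = 0
        y = [np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])]
        dosages = [[[1, 1, 0, 0, 2, 2], [0, 1, 2, 0, 1, 2]]]
        sess = make_session_from_dosages(dosages, phenotypes=y)
        null = fit_null_glm(sess, "outcome ~ 1")
        fed = fast_pooled_gwas(sess, null)
        assert fed.loc[0, "beta"] == pytest.approx(0.0, abs=1e-12)
        assert fed.loc[0, "p"] == pytest.approx(1.0)

    def test_monomorphic_variant_reported_missing(self):
        dosages = [[[0, 0, 0, 0], [0, 1, 2, 1]]]
        sess = make_session_from_dosages(
            dosages, phenotypes=[np.array([0.1, 0.5, -0.2, 1.0])]
        )
        null = fit_null_glm(sess, "outcome ~ 1")
        fed = fast_pooled_gwas(sess, null)
        assert np.isnan(fed.loc[0, "beta"])
        assert np.isfinite(fed.loc[1, "beta"])


class TestPerSnpGlm:
    @pytest.fixture
    def fixture60(self):
        rng = np.random.default_rng(2)
        dosages = [rng.binomial(2, 0.4, size=(3, 60))]
        g = dosages[0][0]
        y = [0.4 * g + rng.normal(size=60)]
        return make_session_from_dosages(dosages, phenotypes=y), g, y[0]

    def test_matches_statsmodels_oracle(self, fixture60):
        sess, g, y = fixture60
        rows = per_snp_glm(sess, "rs1", "outcome ~ 1")
        X = np.column_stack([np.ones(60), g])
        oracle = sm.OLS(y, X).fit()
        assert rows.loc[0, "beta"] == pytest.approx(oracle.params[1], abs=1e-6)
        assert rows.loc[0, "se"] == pytest.approx(oracle.bse[1], abs=1e-6)

    def test_gaussian_family_reduces_to_ols(self, fixture60):
        sess, g, y = fixture60
        rows = per_snp_glm(sess, "rs1", "outcome ~ 1", family="gaussian")
        slope = np.polyfit(g, y, 1)[0]
        assert rows.loc[0, "beta"] == pytest.approx(slope, rel=1e-8)

    def test_monomorphic_site_flagged_missing(self):
        rng = np.random.default_rng(3)
        d1 = np.zeros((1, 30))
        d2 = rng.binomial(2, 0.4, size=(1, 30))
        ys = [rng.normal(size=30), rng.normal(size=30)]
        sess = make_session_from_dosages([d1, d2], phenotypes=ys)
        rows = per_snp_glm(sess, "rs1", "outcome ~ 1")
        assert np.isnan(rows.loc[0, "beta"])
        assert np.isfinite(rows.loc[1, "beta"])


class TestMetaGwas:
    def test_single_site_is_identity(self):
        t = pd.DataFrame(
            {"site": ["a"], "variant_id": ["v"], "EAF": [0.2], "n": [100],
             "beta": [0.5], "se": [0.1], "p": [1e-6]}
        )
        out = meta_gwas(t)
        assert out.loc[0, "beta"] == pytest.approx(0.5)
        assert out.loc[0, "se"] == pytest.approx(0.1)

    def test_equal_se_sites_average(self):
        t = pd.DataFrame(
            {"site": ["a", "b"], "variant_id": ["v", "v"], "EAF": [0.2, 0.2],
             "n": [50, 50], "beta": [1.0, 3.0], "se": [1.0, 1.0],
             "p": [0.5, 0.5]}
        )
        out = meta_gwas(t)
        assert out.loc[0, "beta"] == pytest.approx(2.0)
        assert out.loc[0, "se"] == pytest.approx(1 / np.sqrt(2))

    def test_missing_site_rows_excluded(self):
        t = pd.DataFrame(
            {"site": ["a", "b"], "variant_id": ["v", "v"], "EAF": [0.2, 0.3],
             "n": [50, 60], "beta": [1.0, np.nan], "se": [1.0, np.nan],
             "p": [0.5, np.nan]}
        )
        out = meta_gwas(t)
        assert out.loc[0, "k_sites"] == 1
        assert out.loc[0, "beta"] == pytest.approx(1.0)


class TestStandardization:
    def test_hand_arithmetic(self):
        block = make_block(np.array([[2.0]]))
        z, keep = standardize_genotypes(block, np.array([0.5]))
        assert z[0, 0] == pytest.approx((2 - 1) / np.sqrt(0.5))

    def test_centering_at_expected_dosage(self):
        block = make_block(np.full((1, 4), 1.0))
        z, _ = standardize_genotypes(block, np.array([0.5]))
        np.testing.assert_allclose(z, 0.0)

    def test_monomorphic_excluded(self):
        block = make_block(np.array([[0.0, 0.0], [1.0, 2.0]]))
        z, keep = standardize_genotypes(block, np.array([0.0, 0.5]))
        assert list(keep) == [False, True]
        assert z.shape == (1, 2)


class TestPooledPca:
    def test_single_site_equals_own_svd(self):
        rng = np.random.default_rng(4)
        dosages = [rng.binomial(2, 0.4, size=(10, 25))]
        sess = make_session_from_dosages(dosages)
        res = pooled_pca(sess, k=3)
        af = allele_frequency(sess)
        z, _ = standardize_genotypes(
            sess.processors[0].genotype, af["frequency"].to_numpy()
        )
        sv = np.linalg.svd(z, compute_uv=False)[:3]
        np.testing.assert_allclose(res.singular_values, sv, rtol=1e-10)

    def test_two_sites_match_concatenated_svd(self):
        rng = np.random.default_rng(5)
        dosages = [
            rng.binomial(2, 0.4, size=(12, 20)),
            rng.binomial(2, 0.4, size=(12, 35)),
        ]
        sess = make_session_from_dosages(dosages)
        af = allele_frequency(sess)
        res = pooled_pca(sess, k=5, frequencies=af)
        zs = [
            standardize_genotypes(p.genotype, af["frequency"].to_numpy())[0]
            for p in sess.processors
        ]
        Z = np.hstack(zs)
        u, sv, _ = np.linalg.svd(Z, full_matrices=False)
        np.testing.assert_allclose(res.singular_values, sv[:5], rtol=1e-8)
        # loadings match up to (deterministically fixed) column sign
        for j in range(5):
            col = res.loadings.iloc[:, j].to_numpy()
            ref = u[:, j] * np.sign(u[np.argmax(np.abs(u[:, j]) > 1e-12), j])
            assert min(
                np.max(np.abs(col - u[:, j])), np.max(np.abs(col + u[:, j]))
            ) < 1e-8

    def test_shares_contain_no_per_sample_columns(self):
        rng = np.random.default_rng(6)
        # more samples than variants: local rank = n_variants < n_samples
        dosages = [rng.binomial(2, 0.4, size=(5, 40))]
        sess = make_session_from_dosages(dosages)
        res = pooled_pca(sess, k=2)
        # scores for the site's 40 samples exist only server-side
        scores = sess.processors[0].server_side_store["pca_scores"]
        assert scores.shape == (40, 2)
        assert res.loadings.shape[0] <= 5

    def test_k_beyond_rank_rejected(self):
        rng = np.random.default_rng(7)
        sess = make_session_from_dosages([rng.binomial(2, 0.4, size=(4, 10))])
        with pytest.raises(ValueError, match="exceeds pooled rank"):
            pooled_pca(sess, k=8)


class TestPrs:
    def _session(self, dosages):
        return make_session_from_dosages([dosages])

    def test_zero_weights_give_zero_scores(self):
        sess = self._session(np.array([[0.0, 1.0, 2.0]]))
        model = PGSModel(
            pd.DataFrame(
                {"variant_id": ["rs1"], "effect_allele": ["G"], "weight": [0.0]}
            )
        )
        compute_prs(sess, model)
        np.testing.assert_array_equal(
            sess.processors[0].server_side_store["PRS"], np.zeros(3)
        )

    def test_alt_effect_allele_uses_dosage(self):
        sess = self._session(np.array([[0.0, 1.0, 2.0]]))
        model = PGSModel(
            pd.DataFrame(
                {"variant_id": ["rs1"], "effect_allele": ["G"], "weight": [1.0]}
            )
        )
        compute_prs(sess, model)
        np.testing.assert_array_equal(
            sess.processors[0].server_side_store["PRS"], [0.0, 1.0, 2.0]
        )

    def test_ref_effect_allele_reflects_dosage(self):
        # effect allele = reference, dosage 2 => reflected to 2 - 2 = 0
        sess = self._session(np.array([[2.0, 0.0]]))
        model = PGSModel(
            pd.DataFrame(
                {"variant_id": ["rs1"], "effect_allele": ["A"], "weight": [1.0]}
            )
        )
        compute_prs(sess, model)
        np.testing.assert_array_equal(
            sess.processors[0].server_side_store["PRS"], [0.0, 2.0]
        )

    def test_unmatched_alleles_counted_as_skipped(self):
        sess = self._session(np.array([[1.0, 1.0]]))
        model = PGSModel(
            pd.DataFrame(
                {"variant_id": ["rs1"], "effect_allele": ["T"], "weight": [1.0]}
            )
        )
        summary = compute_prs(sess, model)
        assert summary.loc[0, "n_variants_skipped"] == 1
        assert summary.loc[0, "n_variants_used"] == 0

    def test_no_overlap_rejected(self):
        sess = self._session(np.array([[1.0, 1.0]]))
        model = PGSModel(
            pd.DataFrame(
                {"variant_id": ["zzz"], "effect_allele": ["G"], "weight": [1.0]}
            )
        )
        with pytest.raises(ValueError, match="no overlap"):
            compute_prs(sess, model)
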