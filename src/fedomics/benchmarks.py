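"""Synthetic benchmark scenarios for validating the federated analyses.

Each function builds a fully synthetic multi-site study, runs the
federated computation, and measures it against an independent
single-machine oracle (direct formulas, per-variant full GLM fits by
batched Newton iteration, exhaustive leave-one-out enumeration).  The
scenarios double as the package's reproducibility harness: they are what
the acceptance tests assert on and what ``scripts/acceptance.py``
reports.

Problem sizes are chosen to be informative yet quick on one CPU:
3 sites x 200 samples and 2000 variants for the GWAS benchmarks,
1000 features x 3 sites x 40 samples for the expression benchmark.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from fedomics.data import (
    GenotypeBlock,
    PGSModel,
    simulate_feature_matrix,
    simulate_genotypes,
    simulate_phenotype,
)
from fedomics.federation import PrivacyConfig, create_session, query_audit
from fedomics.gwas import (
    allele_frequency,
    compute_prs,
    fast_pooled_gwas,
    fit_null_glm,
    pooled_pca,
    standardize_genotypes,
)
from fedomics.meta_qc import fisher_combine, ivw_combine, lambda_gc
from fedomics.omics import (
    DesignSpec,
    federated_filter_low_counts,
    meta_features,
    per_feature_lm,
    pooled_feature_lm,
)
from fedomics.privacy import estimate_sensitivity_resampling, laplace_mechanism

__all__ = [
    "pooled_equivalence_errors",
    "fast_vs_full_correlation",
    "type_i_error_rate",
    "parameter_recovery",
    "laplace_variance_ratio",
    "sensitivity_vs_exhaustive",
    "disclosure_gate_checks",
    "meta_statistic_checks",
    "dge_benchmark",
    "prs_checks",
]

_OPEN = PrivacyConfig(dp_enabled=False, maf_threshold=0.0, min_cell_size=1)


def _gaussian_session(
    seed: int,
    sizes=(200, 200, 200),
    n_variants: int = 2000,
    causal=(),
    family: str = "gaussian",
    config: PrivacyConfig = _OPEN,
):
    rng = np.random.default_rng(seed)
    blocks = simulate_genotypes(
        len(sizes), list(sizes), n_variants, fst=0.01,
        seed=int(rng.integers(2**31)),
    )
    phenos = simulate_phenotype(
        blocks,
        causal=list(causal),
        covariate_effects={"age": 0.2, "sex": 0.3},
        family=family,
        noise_sd=1.0,
        seed=int(rng.integers(2**31)),
    )
    session = create_session(
        [(b, p, None, config) for b, p in zip(blocks, phenos)],
        seed=int(rng.integers(2**31)),
    )
    return session, blocks, phenos


def _concat_design(phenos) -> tuple[np.ndarray, np.ndarray]:
    y = np.concatenate([p.outcome for p in phenos])
    X = np.column_stack(
        [np.ones(len(y))]
        + [
            np.concatenate([p.covariates[c] for p in phenos])
            for c in phenos[0].covariates.columns
        ]
    )
    return y, X


def _fast_formula_oracle(G: np.ndarray, y: np.ndarray, X: np.ndarray):
    """Single-machine version of the residual-based scan formulas."""
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ coef
    yc = r - r.mean()
    n = G.shape[1]
    k = X.shape[1] - 1
    B = G @ yc
    S1 = G.sum(axis=1)
    S2 = (G**2).sum(axis=1)
    den1 = S2 - S1**2 / n
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = B / den1
        sigma = (np.sum(yc**2) - beta**2 * den1) / (n - k - 2)
        err = np.sqrt(sigma / den1)
        p = 2.0 * stats.norm.sf(np.abs(beta / err))
    return beta, err, p


def pooled_equivalence_errors(seed: int) -> dict[str, float]:
    """Max relative error of federated vs single-machine computation.

    Four sites of unequal size, all disclosure gates off.  Covers
    allele frequency, the fast pooled GWAS, pooled per-feature OLS and
    pooled-PCA singular values.
    """
    session, blocks, phenos = _gaussian_session(
        seed, sizes=(80, 120, 50, 150), n_variants=300
    )
    G = np.hstack([b.dosages for b in blocks])
    y, X = _concat_design(phenos)

    af = allele_frequency(session)
    freq_direct = G.sum(axis=1) / (2.0 * G.shape[1])
    af_err = np.max(np.abs(af["frequency"].to_numpy() - freq_direct)
                    / np.maximum(freq_direct, 1e-12))

    null = fit_null_glm(session, "outcome ~ age + sex")
    fed = fast_pooled_gwas(session, null)
    beta_o, err_o, _ = _fast_formula_oracle(G, y, X)
    ok = np.isfinite(fed["beta"].to_numpy())
    gwas_err = max(
        np.max(np.abs(fed["beta"].to_numpy()[ok] - beta_o[ok]) / np.abs(beta_o[ok])),
        np.max(np.abs(fed["se"].to_numpy()[ok] - err_o[ok]) / err_o[ok]),
    )

    pca = pooled_pca(session, k=5, frequencies=af)
    Z = np.hstack(
        [standardize_genotypes(b, af["frequency"].to_numpy())[0] for b in blocks]
    )
    sv = np.linalg.svd(Z, compute_uv=False)[:5]
    pca_err = np.max(np.abs(pca.singular_values - sv) / sv)

    rng = np.random.default_rng(seed + 1)
    mats, groups, _ = simulate_feature_matrix(
        50, [80, 120, 50, 150], de_fraction=0.1, n_sites=4,
        seed=int(rng.integers(2**31)),
    )
    fsession = create_session([(None, p, m, _OPEN) for m, p in zip(mats, groups)])
    pooled = pooled_feature_lm(fsession, DesignSpec("outcome"), transform="log_cpm")
    from fedomics.omics import log_cpm

    Yc = np.hstack([log_cpm(m.values) for m in mats])
    Xc = np.column_stack(
        [np.ones(Yc.shape[1]), np.concatenate([p.outcome for p in groups])]
    )
    coef = np.linalg.lstsq(Xc, Yc.T, rcond=None)[0]
    ols_err = np.max(
        np.abs(pooled["effect"].to_numpy() - coef[1])
        / np.maximum(np.abs(coef[1]), 1e-9)
    )
    return {
        "allele_frequency": float(af_err),
        "fast_gwas": float(gwas_err),
        "pca_singular_values": float(pca_err),
        "pooled_feature_ols": float(ols_err),
    }


def _batched_glm_betas(
    G: np.ndarray, X: np.ndarray, y: np.ndarray, family: str
) -> np.ndarray:
    """Independent oracle: full per-variant GLM of y on [X, g] by batched
    Newton iteration (exact OLS for the gaussian family)."""
    m, n = G.shape
    p = X.shape[1] + 1
    designs = np.broadcast_to(X, (m, n, X.shape[1]))
    designs = np.concatenate([designs, G[:, :, None]], axis=2)  # m x n x p
    if family == "gaussian":
        xtx = np.einsum("mnp,mnq->mpq", designs, designs)
        xty = np.einsum("mnp,n->mp", designs, y)
        return np.linalg.solve(xtx, xty[..., None])[:, -1, 0]
    beta = np.zeros((m, p))
    for _ in range(40):
        eta = np.einsum("mnp,mp->mn", designs, beta)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        score = np.einsum("mnp,mn->mp", designs, (y[None, :] - mu))
        info = np.einsum("mnp,mn,mnq->mpq", designs, w, designs)
        step = np.linalg.solve(info, score[..., None])[..., 0]
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    return beta[:, -1]


def fast_vs_full_correlation(
    seed: int, family: str = "gaussian", n_variants: int = 2000
) -> float:
    """Correlation between fast-scan betas and full per-variant GLM betas.

    3 sites x 200 samples, 2 covariates, null phenotype.  The oracle
    fits every variant's full model on the concatenated data.
    """
    session, blocks, phenos = _gaussian_session(
        seed, n_variants=n_variants, family=family
    )
    null = fit_null_glm(session, "outcome ~ age + sex", family=family)
    fed = fast_pooled_gwas(session, null)
    G = np.hstack([b.dosages for b in blocks])
    y, X = _concat_design(phenos)
    full = _batched_glm_betas(G, X, y, family)
    ok = np.isfinite(fed["beta"].to_numpy()) & np.isfinite(full)
    return float(np.corrcoef(fed["beta"].to_numpy()[ok], full[ok])[0, 1])


def type_i_error_rate(seed: int, alpha: float = 0.05) -> tuple[float, int]:
    """Fraction of fast-scan p-values below alpha under the null."""
    session, _, _ = _gaussian_session(seed)
    null = fit_null_glm(session, "outcome ~ age + sex")
    fed = fast_pooled_gwas(session, null)
    p = fed["p"].dropna().to_numpy()
    return float(np.mean(p < alpha)), p.size


def _merge_blocks(a: GenotypeBlock, b: GenotypeBlock) -> GenotypeBlock:
    variants = pd.concat([a.variants, b.variants], ignore_index=True)
    return GenotypeBlock(
        np.vstack([a.dosages, b.dosages]), variants, list(a.sample_ids)
    )


def parameter_recovery(
    seed: int,
    n_replicates: int = 50,
    effect: float = 0.5,
    causal_maf: float = 0.3,
) -> dict[str, float]:
    """Top-hit and coverage rates for one causal variant.

    Each replicate: 3 sites x 200 samples, 150 null variants plus one
    causal variant at MAF 0.3 with effect 0.5 on a gaussian outcome
    (noise sd 1).  Success = the causal variant has the smallest p-value
    and its estimate lies within +/- 2 SE of the truth.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    covered = 0
    both = 0
    for _ in range(n_replicates):
        s1, s2, s3 = (int(rng.integers(2**31)) for _ in range(3))
        null_blocks = simulate_genotypes(3, 200, 150, fst=0.01, seed=s1)
        causal_blocks = simulate_genotypes(
            3, 200, 1, ancestral_maf_range=(causal_maf, causal_maf), seed=s2
        )
        for cb in causal_blocks:
            cb.variants["variant_id"] = ["rs_causal"]
        blocks = [
            _merge_blocks(nb, cb) for nb, cb in zip(null_blocks, causal_blocks)
        ]
        phenos = simulate_phenotype(
            blocks, causal=[("rs_causal", effect)], noise_sd=1.0, seed=s3
        )
        session = create_session([(b, p, None, _OPEN) for b, p in zip(blocks, phenos)])
        null = fit_null_glm(session, "outcome ~ 1")
        fed = fast_pooled_gwas(session, null).set_index("variant_id")
        top = fed["p"].idxmin()
        row = fed.loc["rs_causal"]
        is_top = top == "rs_causal"
        in_ci = abs(row["beta"] - effect) <= 2.0 * row["se"]
        hits += is_top
        covered += in_ci
        both += is_top and in_ci
    return {
        "top_hit_rate": hits / n_replicates,
        "coverage_rate": covered / n_replicates,
        "joint_rate": both / n_replicates,
        "n_replicates": n_replicates,
    }


def laplace_variance_ratio(
    seed: int, sensitivity: float = 1.0, epsilon: float = 3.0, n_draws: int = 10**5
) -> float:
    """Empirical / analytic variance ratio of the Laplace mechanism.

    Analytic variance is 2(Δf/ε)²."""
    rng = np.random.default_rng(seed)
    draws = laplace_mechanism(np.zeros(n_draws), sensitivity, epsilon, rng)
    return float(np.var(draws) / (2.0 * (sensitivity / epsilon) ** 2))


def _exhaustive_sensitivity(fn, data) -> float:
    out = []
    for i in range(len(data)):
        d = np.delete(np.asarray(data, dtype=float), i, axis=0)
        out.append(np.atleast_1d(np.asarray(fn(d), dtype=float)))
    best = 0.0
    for a in out:
        for b in out:
            best = max(best, float(np.sum(np.abs(a - b))))
    return best


def sensitivity_vs_exhaustive(seed: int, n_resamples: int = 200) -> dict[str, float]:
    """Resampled sensitivity of the mean on a 10-record dataset versus the
    exhaustive leave-one-out maximum."""
    rng = np.random.default_rng(seed)
    data = rng.normal(size=10)
    est = estimate_sensitivity_resampling(
        np.mean, data, n_resamples, np.random.default_rng(seed + 1)
    )
    exact = _exhaustive_sensitivity(np.mean, data)
    return {"estimate": est.delta_f, "exhaustive": exact,
            "ratio": est.delta_f / exact}


def disclosure_gate_checks(seed: int) -> dict[str, float]:
    """Default-config gate behaviour on crafted inputs.

    One variant at MAF 0.04 (masked), one at MAF 0.05 (passes), a site
    of 4 samples (blocked by cell suppression at min cell size 5), and
    the audit trail of the blocked query.
    """
    from fedomics.federation import gated_aggregate

    default = PrivacyConfig()  # epsilon 3, MAF 0.05, min cell 5, DP on
    rng = np.random.default_rng(seed)
    n = 100
    g_low = (rng.random(n) < 0.04).astype(float) + (rng.random(n) < 0.04)
    dosages = np.vstack([g_low, rng.binomial(2, 0.3, size=n)]).astype(float)
    mafs = np.array([0.04, 0.05])
    block = GenotypeBlock(
        np.clip(dosages, 0, 2),
        pd.DataFrame(
            {"variant_id": ["low", "ok"], "chrom": "1", "pos": [1, 2],
             "ref": "A", "alt": "G"}
        ),
        [f"i{k}" for k in range(n)],
    )
    session = create_session([(block, None, None, default)], seed=seed)
    res = gated_aggregate(
        session, "site1", np.array([0.04, 0.05]),
        {"kind": "frequency", "mafs": mafs, "sensitivity": 0.0},
        operation="maf_check",
    )
    low_masked = bool(np.isnan(res.value[0]))
    ok_passed = bool(np.isfinite(res.value[1]))
    blocked = gated_aggregate(
        session, "site1", 4.0,
        {"kind": "count", "cell_counts": [4], "sensitivity": 0.0},
        operation="small_group",
    )
    suppressed = blocked.blocked and blocked.reason == "cell_suppression"
    audit = query_audit(session, outcome="blocked")
    audited = len(audit) == 1 and audit[0].operation == "small_group"
    return {
        "maf_004_masked": float(low_masked),
        "maf_005_passed": float(ok_passed),
        "cell_4_blocked": float(suppressed),
        "blocked_query_audited": float(audited),
    }


def meta_statistic_checks(seed: int, n_reps: int = 10**4) -> dict[str, float]:
    """Null-calibration of the combination statistics.

    Fisher statistics from k=4 uniform p-values against chi-square(2k)
    by a KS test; IVW against a hand-computed weighted mean; lambda on
    uniform p-values.
    """
    rng = np.random.default_rng(seed)
    k = 4
    p = rng.random((n_reps, k))
    x2 = np.array([fisher_combine(row).statistic for row in p])
    ks_p = float(stats.kstest(x2, stats.chi2(df=2 * k).cdf).pvalue)

    betas = rng.normal(size=4)
    ses = rng.uniform(0.5, 2.0, size=4)
    comb = ivw_combine(betas, ses)
    w = 1.0 / ses**2
    ivw_err = abs(comb.beta - np.sum(w * betas) / np.sum(w)) + abs(
        comb.se - np.sqrt(1.0 / np.sum(w))
    )
    lam = lambda_gc(rng.random(n_reps))
    return {"fisher_ks_p": ks_p, "ivw_abs_err": float(ivw_err), "lambda_null": lam}


def dge_benchmark(
    seed: int,
    n_seeds: int = 20,
    n_features: int = 1000,
    de_fraction: float = 0.05,
    lfc: float = 1.0,
    bh_level: float = 0.1,
) -> dict[str, float]:
    """Empirical FDR and sensitivity of the meta-mode DGE pipeline.

    Per seed: 1000 features, 3 sites x 40 samples, 5% DE at |LFC| 1;
    per-site log2-CPM OLS, Fisher combination, BH at 0.1.
    """
    rng = np.random.default_rng(seed)
    fdrs, sens = [], []
    for _ in range(n_seeds):
        s = int(rng.integers(2**31))
        mats, groups, de_mask = simulate_feature_matrix(
            n_features, [40, 40, 40], de_fraction=de_fraction,
            log2_fold_change=lfc, n_sites=3, seed=s,
        )
        session = create_session([(None, p, m, _OPEN) for m, p in zip(mats, groups)])
        keep = federated_filter_low_counts(session)
        tables = per_feature_lm(
            session, DesignSpec("outcome"), transform="log_cpm", feature_ids=keep
        )
        res = meta_features(tables, adjust="bh")
        truth = pd.Series(de_mask, index=[f"feat{j + 1}" for j in range(n_features)])
        called = res.loc[res["p_adj"] < bh_level, "feature_id"]
        is_de = truth.loc[called].to_numpy()
        n_called = len(called)
        fdrs.append(0.0 if n_called == 0 else float(np.mean(~is_de)))
        kept_truth = truth.loc[res["feature_id"]]
        n_de = int(kept_truth.sum())
        sens.append(0.0 if n_de == 0 else float(np.sum(is_de)) / n_de)
    return {
        "empirical_fdr": float(np.mean(fdrs)),
        "sensitivity": float(np.mean(sens)),
        "n_seeds": n_seeds,
    }


def prs_checks(seed: int) -> dict[str, float]:
    """PRS exactness and allele harmonization on a crafted 3-variant score.

    Variant w1 scores the alternate allele (dosage used as-is), w2 the
    reference allele (dosage reflected to 2 - X), w3 carries weight 0.
    Verifies the hand-computed dot product, invariance to site
    partitioning, and that the client-side summary carries no
    per-individual values.
    """
    rng = np.random.default_rng(seed)
    n = 30
    dosages = rng.binomial(2, 0.4, size=(3, n)).astype(float)
    variants = pd.DataFrame(
        {"variant_id": ["w1", "w2", "w3"], "chrom": "1", "pos": [1, 2, 3],
         "ref": "A", "alt": "G"}
    )
    model = PGSModel(
        pd.DataFrame(
            {"variant_id": ["w1", "w2", "w3"],
             "effect_allele": ["G", "A", "G"],
             "weight": [0.7, -0.3, 0.0]}
        )
    )
    expected = 0.7 * dosages[0] + (-0.3) * (2.0 - dosages[1])
    one = GenotypeBlock(dosages, variants, [f"i{k}" for k in range(n)])
    sess_one = create_session([(one, None, None, _OPEN)], seed=seed)
    summary = compute_prs(sess_one, model)
    got_one = sess_one.processors[0].server_side_store["PRS"]
    err_one = float(np.max(np.abs(got_one - expected)))

    half = n // 2
    a = GenotypeBlock(dosages[:, :half], variants.copy(), [f"i{k}" for k in range(half)])
    b = GenotypeBlock(
        dosages[:, half:], variants.copy(), [f"i{k}" for k in range(half, n)]
    )
    sess_two = create_session([(a, None, None, _OPEN), (b, None, None, _OPEN)])
    compute_prs(sess_two, model)
    got_two = np.concatenate(
        [p.server_side_store["PRS"] for p in sess_two.processors]
    )
    err_split = float(np.max(np.abs(got_two - expected)))

    payload = summary.select_dtypes(include=[np.number]).to_numpy().ravel()
    leaked = any(
        np.isclose(v, expected, atol=1e-12).any()
        for v in payload
        if v not in (0.0,)
    ) and len(payload) >= n
    return {
        "max_abs_error": err_one,
        "partition_max_abs_error": err_split,
        "per_individual_values_leaked": float(leaked),
    }
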