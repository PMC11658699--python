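"""Federated genomic analyses.

Implements the site/client split for:

* pooled allele frequency — sites return gated (alt count, allele number)
  pairs; the client sums counts and divides by summed allele numbers;
* the exact Hardy–Weinberg test — per-site conditional enumeration of
  heterozygote counts, combined across sites by Fisher's method;
* the fast virtually pooled GWAS — a residual-based score approximation:
  fit the null covariate model once by federated IRLS, then obtain every
  variant's effect from four gated per-variant sums (B = Σ yc·g,
  S1 = Σ g, S2 = Σ g², YC2 = Σ yc²), which reproduces per-variant OLS of
  the centred null residuals on dosage;
* full per-SNP GLMs per site and their inverse-variance meta-analysis;
* pooled PCA by the block singular-value decomposition — each site
  shares only u_i·diag(d_i) (variants × local rank; no per-sample
  columns), the client SVDs the horizontal concatenation, which has
  exactly the singular values of the concatenated standardized matrix;
* server-side polygenic risk scores — per-individual weighted dosage
  sums that never leave the site.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from fedomics.data import GenotypeBlock, PGSModel
from fedomics.federation import DataProcessor, FederationSession, gated_aggregate
from fedomics.meta_qc import fisher_combine, ivw_combine
from fedomics.privacy import estimate_sensitivity_resampling

__all__ = [
    "NullModelFit",
    "PooledPCAResult",
    "allele_frequency",
    "exact_hwe",
    "fit_null_glm",
    "fast_pooled_gwas",
    "per_snp_glm",
    "meta_gwas",
    "standardize_genotypes",
    "pooled_pca",
    "compute_prs",
    "hwe_exact_pvalue",
]

GWAS_COLUMNS = ["variant_id", "chrom", "pos", "EAF", "n", "beta", "se", "p"]


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _parse_formula(formula: str) -> tuple[str | None, list[str]]:
    """Split ``"y ~ a + b"`` into (lhs, [terms]); ``"~1"`` means intercept-only."""
    lhs, _, rhs = formula.partition("~")
    terms = [t.strip() for t in rhs.split("+") if t.strip() and t.strip() != "1"]
    return (lhs.strip() or None), terms


def _design_matrix(proc: DataProcessor, terms: Sequence[str]) -> np.ndarray:
    """Intercept + named covariates; names resolve to phenotype columns
    first, then to server-side stored vectors (e.g. a PRS or PCA score)."""
    if proc.phenotypes is None:
        raise ValueError(f"site {proc.site_id!r} has no phenotype table")
    n = proc.phenotypes.n_samples
    cols = [np.ones(n)]
    for term in terms:
        if term in proc.phenotypes.covariates.columns:
            cols.append(proc.phenotypes.covariates[term].to_numpy(dtype=float))
        elif term in proc.server_side_store:
            vec = np.asarray(proc.server_side_store[term], dtype=float)
            if vec.ndim == 2:  # e.g. PCA scores: expand columns
                cols.extend(vec.T)
                continue
            cols.append(vec)
        else:
            raise KeyError(f"covariate {term!r} not found at site {proc.site_id!r}")
    return np.column_stack(cols)


def _require_shared_variants(session: FederationSession) -> pd.DataFrame:
    blocks = [p.genotype for p in session.processors]
    if any(b is None for b in blocks):
        raise ValueError("every site needs genotype data for this operation")
    first = blocks[0].variants
    for b in blocks[1:]:
        if list(b.variants["variant_id"]) != list(first["variant_id"]):
            raise ValueError("variant lists differ across sites")
    return first


def _site_maf(block: GenotypeBlock) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        freq = np.nansum(block.dosages, axis=1) / (
            2.0 * np.sum(~np.isnan(block.dosages), axis=1)
        )
    return np.minimum(freq, 1.0 - freq)


# ---------------------------------------------------------------------------
# allele frequency
# ---------------------------------------------------------------------------

def allele_frequency(
    session: FederationSession,
    mode: Literal["pooled", "per_site"] = "pooled",
) -> pd.DataFrame:
    """Federated alternate-allele frequency.

    Each site returns gated per-variant (alternate-allele count, allele
    number) pairs — the allele number is twice the non-missing sample
    count, so missing genotypes are excluded.  The client sums counts
    across sites and divides by the summed allele numbers.  Entries
    masked by a site's MAF filter are excluded from that site's
    contribution; variants masked everywhere come back as NaN.
    """
    variants = _require_shared_variants(session)
    rows = []
    for proc in session.processors:
        block = proc.genotype
        nonmiss = np.sum(~np.isnan(block.dosages), axis=1)
        alt = np.nansum(block.dosages, axis=1)
        allele_number = 2.0 * nonmiss
        mafs = _site_maf(block)
        sens = 2.0 if proc.config.dp_enabled else 0.0
        res_alt = gated_aggregate(
            session,
            proc.site_id,
            alt,
            {
                "kind": "count",
                "cell_counts": [block.n_samples],
                "mafs": np.nan_to_num(mafs, nan=0.0),
                "sensitivity": sens,
            },
            operation="allele_frequency",
        )
        res_an = gated_aggregate(
            session,
            proc.site_id,
            allele_number,
            {
                "kind": "count",
                "cell_counts": [block.n_samples],
                "mafs": np.nan_to_num(mafs, nan=0.0),
                "sensitivity": sens,
            },
            operation="allele_frequency",
        )
        if res_alt.blocked or res_an.blocked:
            continue
        rows.append((proc.site_id, res_alt.value, res_an.value, block.n_samples))
    if not rows:
        raise ValueError("all sites blocked by the disclosure gate")

    def _table(alt, an, n):
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = alt / an
        out = variants[["variant_id", "chrom", "pos"]].copy()
        out["alt_count"] = alt
        out["allele_number"] = an
        out["frequency"] = freq
        out["maf"] = np.minimum(freq, 1.0 - freq)
        out["n"] = n
        return out

    if mode == "per_site":
        tables = []
        for site_id, alt, an, n in rows:
            t = _table(alt, an, n)
            t.insert(0, "site", site_id)
            tables.append(t)
        return pd.concat(tables, ignore_index=True)

    alt_stack = np.vstack([r[1] for r in rows])
    an_stack = np.vstack([r[2] for r in rows])
    contrib = ~np.isnan(alt_stack)
    alt_sum = np.where(contrib, alt_stack, 0.0).sum(axis=0)
    an_sum = np.where(contrib, an_stack, 0.0).sum(axis=0)
    alt_sum[an_sum == 0] = np.nan
    an_sum[an_sum == 0] = np.nan
    return _table(alt_sum, an_sum, sum(r[3] for r in rows))


# ---------------------------------------------------------------------------
# exact Hardy-Weinberg test
# ---------------------------------------------------------------------------

def hwe_exact_pvalue(n_het: int, n_hom_minor: int, n_hom_major: int) -> float:
    """Exact conditional Hardy–Weinberg test for one variant.

    Conditions on the observed minor-allele count and enumerates every
    heterozygote count consistent with it; the p-value is the total
    probability of tables no more likely than the observed one.  With
    zero minor-allele copies only one table is attainable and p = 1.
    """
    if min(n_het, n_hom_minor, n_hom_major) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_het + n_hom_minor + n_hom_major
    n_minor = 2 * n_hom_minor + n_het
    n_major = 2 * n_hom_major + n_het
    if n_minor > n_major:
        n_minor, n_major = n_major, n_minor
    if n == 0 or n_minor == 0:
        return 1.0
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    hom_min = (n_minor - hets) // 2
    hom_maj = (n_major - hets) // 2
    valid = hom_maj >= 0
    hets, hom_min, hom_maj = hets[valid], hom_min[valid], hom_maj[valid]
    from scipy.special import gammaln

    logp = (
        gammaln(n + 1)
        - gammaln(hom_min + 1)
        - gammaln(hets + 1)
        - gammaln(hom_maj + 1)
        + hets * np.log(2.0)
        - (gammaln(2 * n + 1) - gammaln(n_minor + 1) - gammaln(n_major + 1))
    )
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    obs = prob[hets == n_het]
    if obs.size == 0:
        raise ValueError("observed heterozygote count inconsistent with allele count")
    return float(min(1.0, np.sum(prob[prob <= obs[0] * (1 + 1e-12)])))


def exact_hwe(
    session: FederationSession,
    controls_only: bool = False,
) -> pd.DataFrame:
    """Per-site exact HWE p-values plus a Fisher-combined p per variant.

    With ``controls_only`` the test uses only samples whose (binary)
    outcome is 0, the usual GWAS-QC convention.  Per-site p-values pass
    the disclosure gate (suppression on the site sample count, the MAF
    mask); masked variants are excluded from the combination.
    """
    variants = _require_shared_variants(session)
    per_site: dict[str, np.ndarray] = {}
    for proc in session.processors:
        dos = proc.genotype.dosages
        if controls_only:
            if proc.phenotypes is None:
                raise ValueError("controls_only requires a phenotype table")
            y = proc.phenotypes.outcome
            if not np.all(np.isin(y[np.isfinite(y)], (0.0, 1.0))):
                raise ValueError("controls_only requires a binary outcome")
            dos = dos[:, y == 0.0]
        pvals = np.empty(dos.shape[0])
        for j in range(dos.shape[0]):
            g = dos[j][~np.isnan(dos[j])]
            n2 = int(np.sum(g == 2))
            n1 = int(np.sum(g == 1))
            n0 = int(np.sum(g == 0))
            pvals[j] = hwe_exact_pvalue(n1, n2, n0)
        res = gated_aggregate(
            session,
            proc.site_id,
            pvals,
            {
                "kind": "statistic",
                "cell_counts": [dos.shape[1]],
                "mafs": np.nan_to_num(_site_maf(proc.genotype), nan=0.0),
                "sensitivity": 0.0,
            },
            operation="exact_hwe",
        )
        if not res.blocked:
            per_site[proc.site_id] = res.value
    out = variants[["variant_id", "chrom", "pos"]].copy()
    for site_id, pv in per_site.items():
        out[f"p_{site_id}"] = pv
    combined = np.full(len(variants), np.nan)
    for j in range(len(variants)):
        ps = [pv[j] for pv in per_site.values() if np.isfinite(pv[j])]
        if ps:
            combined[j] = fisher_combine(ps).p
    out["p_fisher"] = combined
    return out


# ---------------------------------------------------------------------------
# federated null GLM (IRLS)
# ---------------------------------------------------------------------------

@dataclass
class NullModelFit:
    """Converged federated GLM of the outcome on covariates only.

    Coefficients are shared with the client; per-site fitted values and
    response-scale residuals stay in each site's server-side store under
    ``fit_key`` / ``resid_key``.
    """

    coefficients: np.ndarray
    term_names: list[str]
    family: str
    formula: str
    n_total: int
    n_iterations: int
    resid_key: str = "null_resid"
    fit_key: str = "null_fit"

    @property
    def n_covariates(self) -> int:
        """K: covariates excluding the intercept."""
        return len(self.term_names) - 1


def _glm_weights(eta: np.ndarray, family: str) -> tuple[np.ndarray, np.ndarray]:
    """Return (mu, IRLS weight) for the linear predictor."""
    if family == "gaussian":
        return eta, np.ones_like(eta)
    mu = 1.0 / (1.0 + np.exp(-eta))
    return mu, mu * (1.0 - mu)


def fit_null_glm(
    session: FederationSession,
    formula: str,
    family: Literal["gaussian", "binomial"] = "gaussian",
    tol: float = 1e-8,
    max_iter: int = 25,
) -> NullModelFit:
    """Fit the covariate-only model by federated IRLS.

    Each iteration the client broadcasts the current coefficients; each
    site returns the gated weighted cross-products X'WX and X'Wz of the
    working response z, which the client sums and solves.  Convergence
    when the largest coefficient change drops below ``tol``.  After
    convergence every site stores its fitted values and response-scale
    residuals server-side for the fast GWAS stage.
    """
    _, terms = _parse_formula(formula)
    designs, ys = [], []
    for proc in session.processors:
        X = _design_matrix(proc, terms)
        y = proc.phenotypes.outcome
        if np.nanstd(y) == 0:
            raise ValueError(f"site {proc.site_id!r}: outcome is constant")
        if family == "binomial" and not np.all(np.isin(y, (0.0, 1.0))):
            raise ValueError("binomial family requires a 0/1 outcome")
        designs.append(X)
        ys.append(y)
    p = designs[0].shape[1]
    beta = np.zeros(p)
    n_iter = 0
    any_dp = False
    for n_iter in range(1, max_iter + 1):
        xtwx = np.zeros((p, p))
        xtwz = np.zeros(p)
        for proc, X, y in zip(session.processors, designs, ys):
            eta = X @ beta
            mu, w = _glm_weights(eta, family)
            if family == "binomial" and (np.any(mu < 1e-10) or np.any(mu > 1 - 1e-10)):
                raise ValueError(
                    f"site {proc.site_id!r}: fitted probabilities at 0/1 "
                    "(perfect separation?)"
                )
            z = eta + (y - mu) / np.maximum(w, 1e-12)
            agg = np.concatenate([(X.T * w @ X).ravel(), X.T @ (w * z)])
            sens = 0.0
            if proc.config.dp_enabled:
                data = np.column_stack([y, X])

                def fn(d, _family=family, _beta=beta, _p=p):
                    yy, XX = d[:, 0], d[:, 1:]
                    ee = XX @ _beta
                    mm, ww = _glm_weights(ee, _family)
                    zz = ee + (yy - mm) / np.maximum(ww, 1e-12)
                    return np.concatenate(
                        [(XX.T * ww @ XX).ravel(), XX.T @ (ww * zz)]
                    )

                sens = estimate_sensitivity_resampling(
                    fn, data, proc.config.n_resamples, session.rng,
                    gamma=proc.config.gamma,
                ).delta_f
            res = gated_aggregate(
                session,
                proc.site_id,
                agg,
                {
                    "kind": "statistic",
                    "cell_counts": [len(y)],
                    "sensitivity": sens,
                },
                operation="fit_null_glm",
            )
            if res.blocked:
                raise ValueError(
                    f"site {proc.site_id!r} blocked the GLM aggregates "
                    f"({res.reason})"
                )
            any_dp = any_dp or res.dp_applied
            xtwx += res.value[: p * p].reshape(p, p)
            xtwz += res.value[p * p :]
        new_beta = np.linalg.solve(xtwx, xtwz)
        delta = np.max(np.abs(new_beta - beta))
        beta = new_beta
        if delta < tol:
            break
    else:
        if not any_dp:
            raise RuntimeError(f"IRLS did not converge in {max_iter} iterations")
        # noised aggregates keep the iterates jittering at the noise floor;
        # the final iterate is the released estimate
        warnings.warn(
            "IRLS stopped at the iteration cap; coefficient changes are at "
            "the differential-privacy noise floor"
        )
    for proc, X, y in zip(session.processors, designs, ys):
        mu, _ = _glm_weights(X @ beta, family)
        proc.server_side_store["null_fit"] = mu
        proc.server_side_store["null_resid"] = y - mu
    return NullModelFit(
        coefficients=beta,
        term_names=["intercept"] + list(terms),
        family=family,
        formula=formula,
        n_total=sum(len(y) for y in ys),
        n_iterations=n_iter,
    )


# ---------------------------------------------------------------------------
# fast virtually pooled GWAS
# ---------------------------------------------------------------------------

def fast_pooled_gwas(
    session: FederationSession,
    null: NullModelFit,
    center: Literal["pooled", "site"] = "pooled",
) -> pd.DataFrame:
    """Residual-based pooled association scan over all variants.

    Sites centre their null residuals (by the pooled residual mean,
    obtained as one extra gated aggregate, so the result reproduces the
    concatenated-data computation; per-site centring available as an
    option) and return gated per-variant sums B = Σ yc·g, S1 = Σ g,
    S2 = Σ g², YC2 = Σ yc² restricted to non-missing dosages.  The
    client merges and computes::

        DEN1 = S2 − S1²/N,  β = B/DEN1,
        σ  = (YC2 − β²·DEN1) / (N − K − 2),
        SE = sqrt(σ/DEN1),  p = 2·Φ(−|β/SE|).

    Monomorphic variants and variants below the MAF threshold are
    reported as missing.  With DP enabled, Laplace noise is added to
    each per-variant sum with closed-form sensitivities from the bounded
    0/1/2 dosage coding and the site's residual range.
    """
    variants = _require_shared_variants(session)
    resids = []
    for proc in session.processors:
        if null.resid_key not in proc.server_side_store:
            raise ValueError(
                f"site {proc.site_id!r} has no stored null-model residuals"
            )
        resids.append(proc.server_side_store[null.resid_key])

    if center == "pooled":
        tot, cnt = 0.0, 0
        for proc, r in zip(session.processors, resids):
            res = gated_aggregate(
                session,
                proc.site_id,
                float(np.sum(r)),
                {
                    "kind": "statistic",
                    "cell_counts": [len(r)],
                    "sensitivity": float(np.max(np.abs(r)))
                    if proc.config.dp_enabled
                    else 0.0,
                },
                operation="fast_gwas_residual_sum",
            )
            if res.blocked:
                raise ValueError(f"site {proc.site_id!r} blocked residual sum")
            tot += res.value
            cnt += len(r)
        pooled_mean = tot / cnt

    m = len(variants)
    B = np.zeros(m)
    S1 = np.zeros(m)
    S2 = np.zeros(m)
    YC2 = np.zeros(m)
    N = np.zeros(m)
    maf_thresholds = []
    for proc, r in zip(session.processors, resids):
        yc = r - (pooled_mean if center == "pooled" else np.mean(r))
        dos = proc.genotype.dosages
        mask = ~np.isnan(dos)
        g = np.nan_to_num(dos, nan=0.0)
        aggs = {
            "B": (g * mask) @ yc,
            "S1": g.sum(axis=1),
            "S2": (g**2).sum(axis=1),
            "YC2": mask @ (yc**2),
            "n": mask.sum(axis=1).astype(float),
        }
        dp = proc.config.dp_enabled
        ycmax = float(np.max(np.abs(yc))) if dp else 0.0
        sens = {
            "B": 2.0 * ycmax,
            "S1": 2.0,
            "S2": 4.0,
            "YC2": ycmax**2,
            "n": 0.0,
        }
        merged = {}
        for name, vec in aggs.items():
            res = gated_aggregate(
                session,
                proc.site_id,
                vec,
                {
                    "kind": "statistic",
                    "cell_counts": [dos.shape[1]],
                    "sensitivity": sens[name] if dp else 0.0,
                },
                operation=f"fast_gwas_{name}",
            )
            if res.blocked:
                raise ValueError(f"site {proc.site_id!r} blocked {name}")
            merged[name] = res.value
        B += merged["B"]
        S1 += merged["S1"]
        S2 += merged["S2"]
        YC2 += merged["YC2"]
        N += merged["n"]
        maf_thresholds.append(proc.config.maf_threshold)

    with np.errstate(invalid="ignore", divide="ignore"):
        den1 = S2 - S1**2 / N
        beta = B / den1
        sigma = (YC2 - beta**2 * den1) / (N - null.n_covariates - 2)
        err = np.sqrt(sigma / den1)
        pval = 2.0 * stats.norm.sf(np.abs(beta / err))
        eaf = S1 / (2.0 * N)
    poly = den1 > 1e-12
    if not np.any(poly):
        raise ValueError("no polymorphic variants")
    maf = np.minimum(eaf, 1.0 - eaf)
    keep = poly & (maf >= max(maf_thresholds))  # most restrictive site wins
    out = variants[["variant_id", "chrom", "pos"]].copy()
    out["EAF"] = eaf
    out["n"] = N
    out["beta"] = np.where(keep, beta, np.nan)
    out["se"] = np.where(keep, err, np.nan)
    out["p"] = np.where(keep, pval, np.nan)
    return out


# ---------------------------------------------------------------------------
# full per-SNP GLM + meta-analysis
# ---------------------------------------------------------------------------

def per_snp_glm(
    session: FederationSession,
    variant_id: str,
    formula: str,
    family: Literal["gaussian", "binomial"] = "gaussian",
) -> pd.DataFrame:
    """Full (non-approximate) per-site GLM with dosage as a covariate.

    Gaussian family reduces to OLS.  One row per site with the dosage
    effect, its Wald standard error and p-value; monomorphic sites are
    returned with missing estimates.  Rows feed :func:`meta_gwas`.
    """
    import statsmodels.api as sm

    _, terms = _parse_formula(formula)
    rows = []
    for proc in session.processors:
        block = proc.genotype
        idx = block.variant_ids.get_indexer([variant_id])
        if idx[0] < 0:
            raise KeyError(f"variant {variant_id!r} not at site {proc.site_id!r}")
        g = block.dosages[idx[0]]
        keep = ~np.isnan(g)
        X = _design_matrix(proc, terms)[keep]
        y = proc.phenotypes.outcome[keep]
        g = g[keep]
        n = int(keep.sum())
        eaf = float(np.mean(g) / 2.0) if n else np.nan
        maf = min(eaf, 1 - eaf)
        if np.std(g) == 0:
            rows.append((proc.site_id, variant_id, eaf, n, np.nan, np.nan, np.nan))
            continue
        exog = np.column_stack([X, g])
        fam = sm.families.Gaussian() if family == "gaussian" else sm.families.Binomial()
        fit = sm.GLM(y, exog, family=fam).fit()
        est = np.array([fit.params[-1], fit.bse[-1]])
        sens = 0.0
        if proc.config.dp_enabled:
            data = np.column_stack([y, X, g])

            def fn(d, _fam=fam):
                f = sm.GLM(d[:, 0], d[:, 1:], family=_fam).fit()
                return np.array([f.params[-1], f.bse[-1]])

            sens = estimate_sensitivity_resampling(
                fn, data, proc.config.n_resamples, session.rng,
                gamma=proc.config.gamma,
            ).delta_f
        res = gated_aggregate(
            session,
            proc.site_id,
            est,
            {
                "kind": "statistic",
                "cell_counts": [n],
                "mafs": np.full(2, maf),
                "sensitivity": sens,
            },
            operation="per_snp_glm",
        )
        if res.blocked or np.any(np.isnan(res.value)):
            rows.append((proc.site_id, variant_id, eaf, n, np.nan, np.nan, np.nan))
            continue
        b, se = res.value
        p = 2.0 * stats.norm.sf(abs(b / se)) if se > 0 else np.nan
        rows.append((proc.site_id, variant_id, eaf, n, b, se, p))
    return pd.DataFrame(
        rows, columns=["site", "variant_id", "EAF", "n", "beta", "se", "p"]
    )


def meta_gwas(per_site_tables: pd.DataFrame | Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Fixed-effect inverse-variance meta-analysis of per-site GWAS rows.

    Accepts the concatenation (or list) of per-site association tables
    with columns site, variant_id, EAF, n, beta, se, p; combines each
    variant over the sites with non-missing rows.
    """
    if not isinstance(per_site_tables, pd.DataFrame):
        per_site_tables = pd.concat(per_site_tables, ignore_index=True)
    out = []
    for vid, grp in per_site_tables.groupby("variant_id", sort=False):
        ok = grp.dropna(subset=["beta", "se"])
        if len(ok) == 0:
            out.append((vid, np.nan, np.nan, np.nan, np.nan, np.nan, 0))
            continue
        comb = ivw_combine(ok["beta"].to_numpy(), ok["se"].to_numpy())
        n = ok["n"].sum()
        eaf = float(np.average(ok["EAF"], weights=ok["n"]))
        out.append((vid, eaf, n, comb.beta, comb.se, comb.p, comb.k))
    return pd.DataFrame(
        out, columns=["variant_id", "EAF", "n", "beta", "se", "p", "k_sites"]
    )


# ---------------------------------------------------------------------------
# pooled PCA
# ---------------------------------------------------------------------------

def standardize_genotypes(
    block: GenotypeBlock,
    pooled_frequencies: np.ndarray | pd.Series,
) -> tuple[np.ndarray, np.ndarray]:
    """Standardize dosages to (X − 2p) / sqrt(2p(1−p)).

    ``pooled_frequencies`` are alternate-allele frequencies (pooled
    across sites for a meaningful pooled PCA).  Monomorphic or missing-
    frequency variants are excluded; the boolean keep-mask is returned
    alongside the standardized matrix.  Missing dosages become 0 after
    centring (mean imputation).
    """
    p = np.asarray(pooled_frequencies, dtype=float)
    if p.shape != (block.n_variants,):
        raise ValueError("one pooled frequency per variant required")
    keep = np.isfinite(p) & (p > 0.0) & (p < 1.0)
    if not np.any(keep):
        raise ValueError("all variants monomorphic; nothing to standardize")
    pk = p[keep]
    z = (block.dosages[keep] - 2.0 * pk[:, None]) / np.sqrt(2.0 * pk * (1.0 - pk))[
        :, None
    ]
    return np.nan_to_num(z, nan=0.0), keep


@dataclass
class PooledPCAResult:
    loadings: pd.DataFrame  # variants x k, index = variant_id
    singular_values: np.ndarray
    variant_ids: list[str]
    n_per_site: dict[str, int] = field(default_factory=dict)
    scores_key: str = "pca_scores"


def _fix_column_signs(u: np.ndarray) -> np.ndarray:
    """Force the first entry of nonnegligible magnitude in each column to
    be nonnegative, making loading signs deterministic."""
    u = u.copy()
    for j in range(u.shape[1]):
        col = u[:, j]
        nz = np.nonzero(np.abs(col) > 1e-12)[0]
        if nz.size and col[nz[0]] < 0:
            u[:, j] = -col
    return u


def pooled_pca(
    session: FederationSession,
    k: int = 10,
    variant_subset: Sequence[str] | None = None,
    frequencies: pd.DataFrame | None = None,
) -> PooledPCAResult:
    """Pooled PCA of standardized genotypes by the block-SVD method.

    Each site SVDs its standardized block and shares only
    ``u_i·diag(d_i)`` (variants × local rank — no per-sample columns, so
    site data are not reconstructible).  The client concatenates the
    shares horizontally and SVDs the concatenation; its left singular
    vectors are the pooled loadings and its singular values equal those
    of the concatenated standardized matrix.  Sites then project their
    own samples onto the loadings and keep the scores server-side
    (retrievable later as the covariate ``"pca_scores"``).

    ``variant_subset`` restricts to an ancestry-informative id list;
    ``frequencies`` (a pooled allele-frequency table) is computed via
    :func:`allele_frequency` when not supplied.
    """
    variants = _require_shared_variants(session)
    if frequencies is None:
        frequencies = allele_frequency(session)
    freq = frequencies.set_index("variant_id")["frequency"].reindex(
        variants["variant_id"]
    )
    sel = np.ones(len(variants), dtype=bool)
    if variant_subset is not None:
        subset = set(variant_subset)
        missing = subset - set(variants["variant_id"])
        if missing:
            raise KeyError(f"subset variants absent from sites: {sorted(missing)[:5]}")
        sel = variants["variant_id"].isin(subset).to_numpy()
    p = np.where(sel, freq.to_numpy(), np.nan)

    shares = []
    n_per_site = {}
    keep = None
    z_blocks = []
    for proc in session.processors:
        z, kp = standardize_genotypes(proc.genotype, p)
        keep = kp if keep is None else keep
        u, d, _ = np.linalg.svd(z, full_matrices=False)
        share = u * d  # variants x local rank
        sens = 0.0
        if proc.config.dp_enabled:
            idx = np.arange(z.shape[1])

            def fn(cols, _z=z):
                zz = _z[:, np.asarray(cols, dtype=int)]
                uu, dd, _ = np.linalg.svd(zz, full_matrices=False)
                s = _fix_column_signs(uu * dd)
                pad = share.shape[1] - s.shape[1]
                if pad > 0:
                    s = np.hstack([s, np.zeros((s.shape[0], pad))])
                return s[:, : share.shape[1]].ravel()

            sens = estimate_sensitivity_resampling(
                fn, idx, proc.config.n_resamples, session.rng,
                gamma=proc.config.gamma,
            ).delta_f
        res = gated_aggregate(
            session,
            proc.site_id,
            share.ravel(),
            {
                "kind": "statistic",
                "cell_counts": [z.shape[1]],
                "sensitivity": sens,
                "shape": share.shape,
            },
            operation="pooled_pca_share",
        )
        if res.blocked:
            raise ValueError(f"site {proc.site_id!r} blocked its PCA share")
        shares.append(res.value.reshape(share.shape))
        n_per_site[proc.site_id] = z.shape[1]
        z_blocks.append((proc, z))

    merged = np.hstack(shares)
    if k > min(merged.shape):
        raise ValueError(f"k={k} exceeds pooled rank {min(merged.shape)}")
    u, d, _ = np.linalg.svd(merged, full_matrices=False)
    loadings = _fix_column_signs(u[:, :k])
    singvals = d[:k]
    kept_ids = list(variants["variant_id"].to_numpy()[keep])
    for proc, z in z_blocks:
        proc.server_side_store["pca_scores"] = z.T @ loadings
    return PooledPCAResult(
        loadings=pd.DataFrame(
            loadings, index=pd.Index(kept_ids, name="variant_id"),
            columns=[f"PC{i + 1}" for i in range(k)],
        ),
        singular_values=singvals,
        variant_ids=kept_ids,
        n_per_site=n_per_site,
    )


# ---------------------------------------------------------------------------
# polygenic risk scores
# ---------------------------------------------------------------------------

def compute_prs(
    session: FederationSession,
    model: PGSModel,
    store_as: str = "PRS",
) -> pd.DataFrame:
    """Compute per-individual polygenic scores, kept server-side.

    PRS_i = Σ_j X_ij·β_j over the variants shared between the scoring
    model and each site's block.  When the scoring file's effect allele
    is the block's *reference* allele the dosage is reflected to 2 − X
    (harmonization); variants matching neither allele are skipped and
    counted.  The scores are per-individual and therefore disclosive:
    they are stored at each site under ``store_as`` (usable as a
    covariate in later formulas) and the client receives only a
    completion summary.
    """
    summaries = []
    entries = model.entries.set_index("variant_id")
    for proc in session.processors:
        block = proc.genotype
        if block is None:
            raise ValueError(f"site {proc.site_id!r} has no genotype data")
        common = block.variants["variant_id"].isin(entries.index)
        if not common.any():
            raise ValueError(
                f"no overlap between scoring file and site {proc.site_id!r}"
            )
        prs = np.zeros(block.n_samples)
        n_used, n_skipped = 0, 0
        for row_idx in np.nonzero(common.to_numpy())[0]:
            vrow = block.variants.iloc[row_idx]
            e = entries.loc[vrow["variant_id"]]
            dos = np.nan_to_num(block.dosages[row_idx], nan=0.0)
            if e["effect_allele"] == vrow["alt"]:
                prs += float(e["weight"]) * dos
            elif e["effect_allele"] == vrow["ref"]:
                prs += float(e["weight"]) * (2.0 - dos)
            else:
                n_skipped += 1
                continue
            n_used += 1
        proc.server_side_store[store_as] = prs
        res = gated_aggregate(
            session,
            proc.site_id,
            float(n_used),
            {"kind": "count", "sensitivity": 0.0, "score_id": model.score_id},
            operation="compute_prs",
        )
        summaries.append(
            (
                proc.site_id,
                model.score_id,
                store_as,
                int(res.value),
                n_skipped,
                block.n_samples,
            )
        )
    return pd.DataFrame(
        summaries,
        columns=["site", "score_id", "stored_as", "n_variants_used",
                 "n_variants_skipped", "n_samples"],
    )
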