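"""Federated differential expression (DGE) and EWAS.

The federated contribution is a per-feature-linear-model-plus-meta
scaffold: abundances are transformed (log2 CPM for counts, M-values for
methylation betas), each feature is fit by ordinary least squares on a
group + covariates design, and results are either pooled exactly via
gated per-site cross-product aggregates or combined across sites by
Fisher's method with Bonferroni/Benjamini–Hochberg adjustment.
Preprocessing covers CPM-based low-count filtering (federated as the
intersection of per-site keep-lists, so every site models the same
features) and per-site winsorization.  Empirical-Bayes moderation,
dispersion estimation and normalization-factor estimation are out of
scope; the per-feature OLS is deliberately plain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from fedomics.data import FeatureMatrix
from fedomics.federation import DataProcessor, FederationSession, gated_aggregate
from fedomics.meta_qc import adjust_pvalues, fisher_combine
from fedomics.privacy import estimate_sensitivity_resampling

__all__ = [
    "DesignSpec",
    "filter_low_counts",
    "federated_filter_low_counts",
    "winsorize",
    "log_cpm",
    "mvalues",
    "per_feature_lm",
    "pooled_feature_lm",
    "meta_features",
]

FEATURE_RESULT_COLUMNS = [
    "feature_id", "effect", "se", "t", "p", "mean_abundance", "n", "site",
]


@dataclass
class DesignSpec:
    """Two-group design with optional covariates.

    ``group`` names the binary grouping variable (a phenotype covariate
    column, or the phenotype outcome itself when named "outcome");
    ``covariates`` are additional adjustment columns.  The contrast of
    interest is always the group coefficient.
    """

    group: str
    covariates: tuple[str, ...] = field(default_factory=tuple)

    def matrix(self, proc: DataProcessor) -> np.ndarray:
        pheno = proc.phenotypes
        if pheno is None:
            raise ValueError(f"site {proc.site_id!r} has no phenotype table")

        def col(name: str) -> np.ndarray:
            if name == "outcome":
                return pheno.outcome
            if name in pheno.covariates.columns:
                return pheno.covariates[name].to_numpy(dtype=float)
            raise KeyError(f"variable {name!r} not found at site {proc.site_id!r}")

        g = col(self.group)
        if len(np.unique(g[np.isfinite(g)])) < 2:
            raise ValueError(
                f"grouping variable {self.group!r} has < 2 levels at site "
                f"{proc.site_id!r}"
            )
        cols = [np.ones_like(g), g] + [col(c) for c in self.covariates]
        return np.column_stack(cols)

    def group_counts(self, proc: DataProcessor) -> list[int]:
        pheno = proc.phenotypes
        g = (
            pheno.outcome
            if self.group == "outcome"
            else pheno.covariates[self.group].to_numpy(dtype=float)
        )
        g = g[np.isfinite(g)]
        levels, counts = np.unique(g, return_counts=True)
        if len(levels) > 10:  # continuous exposure: no group cells to suppress
            return [len(g)]
        return counts.tolist()


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def _cpm(values: np.ndarray) -> np.ndarray:
    libsize = values.sum(axis=0)
    if np.any(libsize == 0):
        raise ValueError("sample with zero library size")
    return values / libsize * 1e6


def filter_low_counts(
    features: FeatureMatrix,
    min_cpm: float = 1.0,
    min_sample_fraction: float = 0.5,
) -> list[str]:
    """Ids of features with CPM > min_cpm in at least ``min_sample_fraction``
    of the samples."""
    if features.value_kind != "counts":
        raise ValueError("low-count filtering applies to count matrices")
    frac = np.mean(_cpm(features.values) > min_cpm, axis=1)
    keep = frac >= min_sample_fraction
    return list(features.feature_ids[keep])


def federated_filter_low_counts(
    session: FederationSession,
    min_cpm: float = 1.0,
    min_sample_fraction: float = 0.5,
) -> list[str]:
    """Intersection of the per-site keep-lists, in the shared feature order."""
    keep: set[str] | None = None
    order: list[str] = []
    for proc in session.processors:
        if proc.features is None:
            raise ValueError(f"site {proc.site_id!r} has no feature matrix")
        ids = filter_low_counts(proc.features, min_cpm, min_sample_fraction)
        if keep is None:
            keep, order = set(ids), list(proc.features.feature_ids)
        else:
            keep &= set(ids)
    return [f for f in order if f in keep]


def winsorize(features: FeatureMatrix, tail_fraction: float = 0.005) -> FeatureMatrix:
    """Clamp each feature's values at its empirical tail quantiles.

    Values below the ``tail_fraction`` quantile are set to that
    quantile, symmetrically above the ``1 − tail_fraction`` quantile;
    applied per feature, per site independently.  ``tail_fraction = 0``
    is the identity.
    """
    if not 0 <= tail_fraction < 0.5:
        raise ValueError("tail_fraction must lie in [0, 0.5)")
    vals = features.values
    if tail_fraction == 0:
        clipped = vals.copy()
    else:
        lo = np.quantile(vals, tail_fraction, axis=1, keepdims=True)
        hi = np.quantile(vals, 1 - tail_fraction, axis=1, keepdims=True)
        clipped = np.clip(vals, lo, hi)
        if features.value_kind == "counts":
            clipped = np.round(clipped)
    return FeatureMatrix(
        clipped, features.features.copy(), list(features.sample_ids),
        value_kind=features.value_kind,
    )


def log_cpm(values: np.ndarray) -> np.ndarray:
    """log2(CPM + 0.5): variance-stabilising transform for count data."""
    return np.log2(_cpm(values) + 0.5)


def mvalues(betas: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Methylation beta-values to M-values: log2(beta / (1 − beta))."""
    b = np.clip(betas, eps, 1 - eps)
    return np.log2(b / (1.0 - b))


def _transform(features: FeatureMatrix, transform: str) -> np.ndarray:
    if transform == "log_cpm":
        return log_cpm(features.values)
    if transform == "mvalue":
        return mvalues(features.values)
    if transform == "identity":
        return features.values.astype(float)
    raise ValueError(f"unknown transform {transform!r}")


# ---------------------------------------------------------------------------
# per-feature linear models
# ---------------------------------------------------------------------------

def _ols_all_features(
    Y: np.ndarray, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-row OLS of Y (features x n) on X (n x p).

    Returns (effect, se, t, p) for the group column (column 1 of X),
    with t-based p at n − p residual df.
    """
    n, p = X.shape
    if n <= p:
        raise ValueError("not enough samples for the design")
    xtx_inv = np.linalg.inv(X.T @ X)
    coef = Y @ X @ xtx_inv  # features x p
    resid = Y - coef @ X.T
    df = n - p
    sigma2 = np.sum(resid**2, axis=1) / df
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    effect = coef[:, 1]
    with np.errstate(invalid="ignore", divide="ignore"):
        t = effect / se
        pv = 2.0 * stats.t.sf(np.abs(t), df)
    return effect, se, t, pv


def per_feature_lm(
    session: FederationSession,
    design: DesignSpec,
    transform: Literal["log_cpm", "identity", "mvalue"] = "identity",
    feature_ids: Sequence[str] | None = None,
) -> list[pd.DataFrame]:
    """Per-site OLS of transformed abundance on the design, per feature.

    Returns one association table per site (gated: suppression on the
    group cell sizes; with DP enabled, Laplace noise on the effect
    vector with resampling-estimated sensitivity, t statistics and p
    recomputed from the noised effects).
    """
    tables = []
    for proc in session.processors:
        if proc.features is None:
            raise ValueError(f"site {proc.site_id!r} has no feature matrix")
        fm = proc.features
        Y = _transform(fm, transform)
        sel = np.ones(fm.n_features, dtype=bool)
        if feature_ids is not None:
            sel = np.asarray(fm.feature_ids.isin(feature_ids))
        Y = Y[sel]
        ids = fm.feature_ids[sel]
        X = design.matrix(proc)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(f"rank-deficient design at site {proc.site_id!r}")
        effect, se, t, pv = _ols_all_features(Y, X)
        sens = 0.0
        if proc.config.dp_enabled:
            idx = np.arange(X.shape[0])

            def fn(rows, _Y=Y, _X=X):
                r = np.asarray(rows, dtype=int)
                return _ols_all_features(_Y[:, r], _X[r])[0]

            sens = estimate_sensitivity_resampling(
                fn, idx, proc.config.n_resamples, session.rng,
                gamma=proc.config.gamma,
            ).delta_f
        res = gated_aggregate(
            session,
            proc.site_id,
            effect,
            {
                "kind": "statistic",
                "cell_counts": design.group_counts(proc),
                "sensitivity": sens,
            },
            operation="per_feature_lm",
        )
        if res.blocked:
            raise ValueError(
                f"site {proc.site_id!r} blocked per-feature results ({res.reason})"
            )
        effect = res.value
        if res.dp_applied:
            with np.errstate(invalid="ignore", divide="ignore"):
                t = effect / se
                pv = 2.0 * stats.t.sf(np.abs(t), X.shape[0] - X.shape[1])
        tables.append(
            pd.DataFrame(
                {
                    "feature_id": ids,
                    "effect": effect,
                    "se": se,
                    "t": t,
                    "p": pv,
                    "mean_abundance": Y.mean(axis=1),
                    "n": X.shape[0],
                    "site": proc.site_id,
                }
            )
        )
    return tables


def pooled_feature_lm(
    session: FederationSession,
    design: DesignSpec,
    transform: Literal["log_cpm", "identity", "mvalue"] = "identity",
    feature_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Exact pooled OLS per feature via gated per-site cross-products.

    Sites return X'X, X'y (per feature), y'y (per feature) and n; the
    client solves the pooled normal equations, which equals
    single-machine OLS on the concatenated samples when DP is off.
    A site whose feature is entirely missing is excluded from that
    feature's aggregates (its pooled n reflects the exclusion).
    """
    per_site = []
    p = None
    for proc in session.processors:
        fm = proc.features
        if fm is None:
            raise ValueError(f"site {proc.site_id!r} has no feature matrix")
        Y = _transform(fm, transform)
        sel = np.ones(fm.n_features, dtype=bool)
        if feature_ids is not None:
            sel = np.asarray(fm.feature_ids.isin(feature_ids))
        Y = Y[sel]
        ids = list(fm.feature_ids[sel])
        X = design.matrix(proc)
        p = X.shape[1]
        present = ~np.any(np.isnan(Y), axis=1)
        Y0 = np.nan_to_num(Y, nan=0.0)
        xtx = X.T @ X
        xty = Y0 @ X  # features x p
        yty = np.sum(Y0**2, axis=1)
        agg = np.concatenate([xtx.ravel(), xty.ravel(), yty])
        sens = 0.0
        if proc.config.dp_enabled:
            idx = np.arange(X.shape[0])

            def fn(rows, _Y=Y0, _X=X):
                r = np.asarray(rows, dtype=int)
                XX, YY = _X[r], _Y[:, r]
                return np.concatenate(
                    [(XX.T @ XX).ravel(), (YY @ XX).ravel(), np.sum(YY**2, axis=1)]
                )

            sens = estimate_sensitivity_resampling(
                fn, idx, proc.config.n_resamples, session.rng,
                gamma=proc.config.gamma,
            ).delta_f
        res = gated_aggregate(
            session,
            proc.site_id,
            agg,
            {
                "kind": "statistic",
                "cell_counts": design.group_counts(proc),
                "sensitivity": sens,
            },
            operation="pooled_feature_lm",
        )
        if res.blocked:
            raise ValueError(
                f"site {proc.site_id!r} blocked pooled aggregates ({res.reason})"
            )
        v = res.value
        per_site.append(
            {
                "ids": ids,
                "xtx": v[: p * p].reshape(p, p),
                "xty": v[p * p : p * p + len(ids) * p].reshape(len(ids), p),
                "yty": v[p * p + len(ids) * p :],
                "present": present,
                "n": X.shape[0],
                "Ymean_sum": Y0.sum(axis=1),
            }
        )
    ids = per_site[0]["ids"]
    for s in per_site[1:]:
        if s["ids"] != ids:
            raise ValueError("feature lists differ across sites")
    n_feat = len(ids)
    rows = []
    for j in range(n_feat):
        xtx = np.zeros((p, p))
        xty = np.zeros(p)
        yty = 0.0
        n = 0
        ysum = 0.0
        for s in per_site:
            if not s["present"][j]:
                continue
            xtx += s["xtx"]
            xty += s["xty"][j]
            yty += s["yty"][j]
            n += s["n"]
            ysum += s["Ymean_sum"][j]
        if n <= p:
            rows.append((ids[j], *([np.nan] * 4), np.nan, n))
            continue
        try:
            xtx_inv = np.linalg.inv(xtx)
        except np.linalg.LinAlgError:
            raise ValueError("pooled design is rank-deficient")
        coef = xtx_inv @ xty
        rss = yty - coef @ xty
        df = n - p
        sigma2 = max(rss, 0.0) / df
        se = np.sqrt(sigma2 * xtx_inv[1, 1])
        with np.errstate(invalid="ignore", divide="ignore"):
            t = coef[1] / se
            pv = 2.0 * stats.t.sf(abs(t), df)
        rows.append((ids[j], coef[1], se, t, pv, ysum / n, n))
    out = pd.DataFrame(
        rows, columns=["feature_id", "effect", "se", "t", "p", "mean_abundance", "n"]
    )
    out["site"] = "pooled"
    return out


def meta_features(
    per_site_tables: Sequence[pd.DataFrame],
    method: Literal["fisher"] = "fisher",
    adjust: Literal["bonferroni", "bh"] = "bh",
) -> pd.DataFrame:
    """Fisher-method combination of per-site per-feature p-values.

    Features are matched by id across sites; the combined p is adjusted
    by the chosen multiple-testing procedure over the retained features.
    """
    if method != "fisher":
        raise ValueError("only Fisher's method is supported")
    merged = pd.concat(per_site_tables, ignore_index=True)
    rows = []
    for fid, grp in merged.groupby("feature_id", sort=False):
        ps = grp["p"].dropna().to_numpy()
        if ps.size == 0:
            rows.append((fid, np.nan, np.nan, np.nan, 0))
            continue
        comb = fisher_combine(ps)
        rows.append((fid, comb.statistic, comb.df, comb.p, comb.k))
    out = pd.DataFrame(rows, columns=["feature_id", "statistic", "df", "p", "k_sites"])
    out["p_adj"] = adjust_pvalues(out["p"].to_numpy(), method=adjust)
    out["site"] = "meta"
    return out
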