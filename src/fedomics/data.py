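"""Data model, file I/O and synthetic-data generators.

Containers are oriented features × samples throughout (variants × samples
for genotypes), matching the block-SVD algebra used for pooled PCA.
Genotypes are alternate-allele dosages coded 0/1/2 with NaN for missing.

The simulators generate multi-site genotype panels (Balding–Nichols
model: site allele frequencies drawn around an ancestral frequency with
divergence F_ST, genotypes binomial so each site is in Hardy–Weinberg
equilibrium), GLM phenotypes, negative-binomial RNA-seq counts and
Beta-distributed methylation values — everything downstream analyses
need, with no external downloads.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeBlock",
    "PhenotypeTable",
    "FeatureMatrix",
    "PGSModel",
    "read_vcf",
    "read_dosage_matrix",
    "write_dosage_matrix",
    "read_pgs_scorefile",
    "read_phenotypes",
    "write_phenotypes",
    "read_feature_matrix",
    "write_feature_matrix",
    "simulate_genotypes",
    "simulate_phenotype",
    "simulate_feature_matrix",
]

VARIANT_COLUMNS = ["variant_id", "chrom", "pos", "ref", "alt"]


@dataclass
class GenotypeBlock:
    """Variants × samples alternate-allele dosage matrix with metadata.

    ``dosages`` holds values in {0, 1, 2} (float, NaN = missing genotype).
    ``variants`` is a table with columns variant_id, chrom, pos, ref, alt;
    variant ids are unique within a block.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D variants x samples matrix")
        if self.dosages.shape != (len(self.variants), len(self.sample_ids)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.variants)} variants x {len(self.sample_ids)} samples"
            )
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.all(np.isin(vals, (0.0, 1.0, 2.0))):
            raise ValueError("dosages must take values in {0, 1, 2} or NaN")
        if self.variants["variant_id"].duplicated().any():
            dup = self.variants["variant_id"][self.variants["variant_id"].duplicated()]
            raise ValueError(f"duplicate variant ids: {sorted(set(dup))}")

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[1]

    @property
    def variant_ids(self) -> pd.Index:
        return pd.Index(self.variants["variant_id"])


@dataclass
class PhenotypeTable:
    """Per-sample outcome and named covariates (one row per sample)."""

    sample_ids: list[str]
    outcome: np.ndarray
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.outcome = np.asarray(self.outcome, dtype=float)
        if self.outcome.shape != (len(self.sample_ids),):
            raise ValueError("outcome length must equal number of samples")
        if len(self.covariates) not in (0, len(self.sample_ids)):
            raise ValueError("covariate rows must equal number of samples")
        if len(self.covariates) == 0:
            self.covariates = pd.DataFrame(index=range(len(self.sample_ids)))

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass
class FeatureMatrix:
    """Features × samples value matrix (counts, methylation betas, ...)."""

    values: np.ndarray
    features: pd.DataFrame
    sample_ids: list[str]
    value_kind: Literal["counts", "methylation_beta", "continuous"] = "continuous"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.features), len(self.sample_ids)):
            raise ValueError("value matrix shape must match features x samples")
        finite = self.values[np.isfinite(self.values)]
        if self.value_kind == "counts":
            if finite.size and (np.any(finite < 0) or np.any(finite != np.round(finite))):
                raise ValueError("counts must be nonnegative integers")
        elif self.value_kind == "methylation_beta":
            if finite.size and (np.any(finite < 0) or np.any(finite > 1)):
                raise ValueError("methylation beta-values must lie in [0, 1]")

    @property
    def feature_ids(self) -> pd.Index:
        return pd.Index(self.features["feature_id"])

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class PGSModel:
    """Polygenic-score weights: one (variant, effect allele, weight) per row."""

    entries: pd.DataFrame  # columns: variant_id, effect_allele, weight
    score_id: str = "PGS"
    source: str = "unknown"

    def __post_init__(self) -> None:
        required = {"variant_id", "effect_allele", "weight"}
        missing = required - set(self.entries.columns)
        if missing:
            raise ValueError(f"scoring table missing columns: {sorted(missing)}")
        if self.entries["variant_id"].duplicated().any():
            raise ValueError("duplicate variant ids in scoring file")
        if not np.all(np.isfinite(self.entries["weight"].to_numpy(dtype=float))):
            raise ValueError("effect weights must be finite")

    @property
    def n_variants(self) -> int:
        return len(self.entries)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path) -> tuple[GenotypeBlock, int]:
    """Read a VCF into a :class:`GenotypeBlock` of alternate-allele dosages.

    Only biallelic records are converted; multi-allelic records are
    dropped and counted.  Missing genotypes (``./.``) become NaN.

    Returns
    -------
    (block, n_dropped)
        The genotype block and the number of multi-allelic records dropped.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    rows, meta = [], []
    n_dropped = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_dropped += 1
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = rec.gt_types.astype(float)
        dos = np.where(gt == 3, 2.0, gt)
        dos[gt == 2] = np.nan
        rows.append(dos)
        vid = rec.ID if rec.ID else f"{rec.CHROM}:{rec.POS}:{rec.REF}:{rec.ALT[0]}"
        meta.append((vid, rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
    vcf.close()
    if not rows:
        raise ValueError(f"no biallelic records found in {path}")
    variants = pd.DataFrame(meta, columns=VARIANT_COLUMNS)
    block = GenotypeBlock(np.vstack(rows), variants, sample_ids)
    return block, n_dropped


def _sidecar_path(path: str | Path) -> Path:
    p = Path(path)
    return p.with_name(p.stem + ".variants.tsv")


def write_dosage_matrix(block: GenotypeBlock, path: str | Path) -> None:
    """Write a block as tab-delimited variants x samples plus a variant sidecar."""
    df = pd.DataFrame(
        block.dosages, index=block.variants["variant_id"], columns=block.sample_ids
    )
    df.index.name = "variant_id"
    df.to_csv(path, sep="\t", na_rep="NA")
    block.variants.to_csv(_sidecar_path(path), sep="\t", index=False)


def read_dosage_matrix(path: str | Path) -> GenotypeBlock:
    """Read a tab-delimited dosage matrix written by :func:`write_dosage_matrix`."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    variants = pd.read_csv(_sidecar_path(path), sep="\t", dtype={"variant_id": str})
    if list(variants["variant_id"]) != [str(v) for v in df.index]:
        raise ValueError("variant sidecar does not match dosage matrix rows")
    dosages = df.to_numpy(dtype=float)
    vals = dosages[~np.isnan(dosages)]
    if vals.size and not np.all(np.isin(vals, (0.0, 1.0, 2.0))):
        raise ValueError("dosage matrix contains values outside {0, 1, 2, NA}")
    return GenotypeBlock(dosages, variants, [str(c) for c in df.columns])


def write_phenotypes(table: PhenotypeTable, path: str | Path) -> None:
    """Write a phenotype table: sample_id, outcome, then covariates."""
    df = pd.DataFrame({"sample_id": table.sample_ids, "outcome": table.outcome})
    for col in table.covariates.columns:
        df[col] = table.covariates[col].to_numpy()
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Read a tab-delimited phenotype table written by :func:`write_phenotypes`."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    if "sample_id" not in df.columns or "outcome" not in df.columns:
        raise ValueError("phenotype table needs sample_id and outcome columns")
    covs = df.drop(columns=["sample_id", "outcome"]).reset_index(drop=True)
    return PhenotypeTable(
        [str(s) for s in df["sample_id"]], df["outcome"].to_numpy(dtype=float), covs
    )


def write_feature_matrix(matrix: FeatureMatrix, path: str | Path) -> None:
    """Write a features x samples matrix with its annotation sidecar."""
    df = pd.DataFrame(
        matrix.values, index=matrix.features["feature_id"], columns=matrix.sample_ids
    )
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t", na_rep="NA")
    matrix.features.to_csv(_sidecar_path(path), sep="\t", index=False)


def read_feature_matrix(
    path: str | Path,
    value_kind: Literal["counts", "methylation_beta", "continuous"] = "continuous",
) -> FeatureMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        features = pd.read_csv(sidecar, sep="\t", dtype={"feature_id": str})
    else:
        features = pd.DataFrame({"feature_id": [str(i) for i in df.index]})
    return FeatureMatrix(
        df.to_numpy(dtype=float),
        features,
        [str(c) for c in df.columns],
        value_kind=value_kind,
    )


_PGS_COLUMN_ALIASES = {
    "variant_id": ["rsID", "rsid", "variant_id", "hm_rsID"],
    "effect_allele": ["effect_allele", "hm_effect_allele", "A1"],
    "weight": ["effect_weight", "weight", "beta"],
}


def read_pgs_scorefile(path: str | Path, score_id: str | None = None) -> PGSModel:
    """Read a PGS-Catalog-style tab-delimited scoring file.

    Header metadata lines starting with ``#`` are skipped.  The column
    header must include a variant id (``rsID``), ``effect_allele`` and
    ``effect_weight`` (standard harmonized-scorefile aliases accepted).
    """
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if not ln.startswith("#")]
    df = pd.read_csv(io.StringIO("\n".join(lines)), sep="\t", dtype=str)
    resolved = {}
    for canon, aliases in _PGS_COLUMN_ALIASES.items():
        found = [a for a in aliases if a in df.columns]
        if not found:
            raise ValueError(f"scoring file missing required column for {canon!r}")
        resolved[canon] = found[0]
    entries = pd.DataFrame(
        {
            "variant_id": df[resolved["variant_id"]],
            "effect_allele": df[resolved["effect_allele"]],
            "weight": df[resolved["weight"]].astype(float),
        }
    )
    return PGSModel(entries, score_id=score_id or Path(path).stem, source=str(path))


# ---------------------------------------------------------------------------
# Simulators
# ---------------------------------------------------------------------------

def simulate_genotypes(
    n_sites: int,
    samples_per_site: int | Sequence[int],
    n_variants: int,
    ancestral_maf_range: tuple[float, float] = (0.05, 0.5),
    fst: float = 0.0,
    seed: int | None = None,
    missing_rate: float = 0.0,
) -> list[GenotypeBlock]:
    """Simulate structured multi-site genotype panels.

    Ancestral alternate-allele frequencies p_j are uniform on
    ``ancestral_maf_range``; per-site frequencies follow the
    Balding–Nichols Beta(p(1−F)/F, (1−p)(1−F)/F) model when ``fst`` > 0
    (all sites share p_j when F = 0); genotypes are Binomial(2, site
    frequency), i.e. in Hardy–Weinberg equilibrium within site.  All
    sites share the same variant list in the same order.
    """
    lo, hi = ancestral_maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("ancestral MAF range must lie within (0, 0.5]")
    if not 0 <= fst < 1:
        raise ValueError("fst must lie in [0, 1)")
    if np.isscalar(samples_per_site):
        samples_per_site = [int(samples_per_site)] * n_sites
    if len(samples_per_site) != n_sites:
        raise ValueError("samples_per_site length must equal n_sites")
    rng = np.random.default_rng(seed)
    p_anc = rng.uniform(lo, hi, size=n_variants)
    variants = pd.DataFrame(
        {
            "variant_id": [f"rs{j + 1}" for j in range(n_variants)],
            "chrom": (np.arange(n_variants) % 22 + 1).astype(str),
            "pos": np.arange(1, n_variants + 1) * 1000,
            "ref": "A",
            "alt": "G",
        }
    )
    blocks = []
    offset = 0
    for s in range(n_sites):
        n = samples_per_site[s]
        if fst > 0:
            a = p_anc * (1 - fst) / fst
            b = (1 - p_anc) * (1 - fst) / fst
            p_site = rng.beta(a, b)
        else:
            p_site = p_anc
        dos = rng.binomial(2, p_site[:, None], size=(n_variants, n)).astype(float)
        if missing_rate > 0:
            miss = rng.random(dos.shape) < missing_rate
            dos[miss] = np.nan
        ids = [f"site{s + 1}_ind{offset + k + 1}" for k in range(n)]
        offset += n
        blocks.append(GenotypeBlock(dos, variants.copy(), ids))
    return blocks


def simulate_phenotype(
    blocks: Sequence[GenotypeBlock],
    causal: Sequence[tuple[str, float]] = (),
    covariate_effects: dict[str, float] | None = None,
    family: Literal["gaussian", "binomial"] = "gaussian",
    noise_sd: float = 1.0,
    baseline: float = 0.0,
    seed: int | None = None,
) -> list[PhenotypeTable]:
    """Simulate per-site phenotypes from a GLM on dosages and covariates.

    The linear predictor is ``baseline + Σ effect·dosage + Σ γ·covariate``
    with standard-normal covariates generated per sample (named by the
    keys of ``covariate_effects``).  Gaussian outcomes add
    Normal(0, noise_sd) noise; binomial outcomes are Bernoulli with the
    inverse-logit of the predictor (``baseline`` then acts as the
    baseline logit).  Missing causal dosages contribute 0.
    """
    rng = np.random.default_rng(seed)
    covariate_effects = covariate_effects or {}
    tables = []
    for block in blocks:
        n = block.n_samples
        eta = np.full(n, float(baseline))
        for vid, eff in causal:
            idx = block.variant_ids.get_indexer([vid])
            if idx[0] < 0:
                raise KeyError(f"causal variant {vid} not in block")
            g = np.nan_to_num(block.dosages[idx[0]], nan=0.0)
            eta = eta + eff * g
        covs = {}
        for name, gamma in covariate_effects.items():
            x = rng.standard_normal(n)
            covs[name] = x
            eta = eta + gamma * x
        if family == "gaussian":
            y = eta + rng.normal(0.0, noise_sd, size=n)
        elif family == "binomial":
            p = 1.0 / (1.0 + np.exp(-eta))
            y = rng.binomial(1, p).astype(float)
        else:
            raise ValueError(f"unknown family {family!r}")
        tables.append(
            PhenotypeTable(list(block.sample_ids), y, pd.DataFrame(covs))
        )
    return tables


def simulate_feature_matrix(
    n_features: int,
    samples_per_site: int | Sequence[int],
    de_fraction: float = 0.0,
    log2_fold_change: float = 1.0,
    dispersion: float = 0.2,
    kind: Literal["counts", "methylation_beta"] = "counts",
    n_sites: int = 1,
    seed: int | None = None,
    base_mean: float = 100.0,
    beta_precision: float = 30.0,
) -> tuple[list[FeatureMatrix], list[PhenotypeTable], np.ndarray]:
    """Simulate per-site feature matrices with a two-group design.

    Counts are NegativeBinomial with feature mean ``μ_f · 2^(LFC·group)``
    and gamma-mixture dispersion; methylation beta-values are
    Beta-distributed with the group shifting the mean on the logit scale
    by ``log2_fold_change``.  Group assignment is balanced within site.

    Returns
    -------
    (features, phenotypes, de_mask)
        Per-site feature matrices, matching phenotype tables whose
        outcome is the 0/1 group label, and the boolean truth mask of
        differentially expressed features.
    """
    if np.isscalar(samples_per_site):
        samples_per_site = [int(samples_per_site)] * n_sites
    rng = np.random.default_rng(seed)
    n_de = int(round(de_fraction * n_features))
    de_mask = np.zeros(n_features, dtype=bool)
    de_mask[rng.choice(n_features, size=n_de, replace=False)] = True
    # half the DE features go up, half down
    sign = np.where(rng.random(n_features) < 0.5, 1.0, -1.0)
    lfc = np.where(de_mask, sign * log2_fold_change, 0.0)
    mu0 = rng.lognormal(mean=np.log(base_mean), sigma=1.0, size=n_features)
    feats_meta = pd.DataFrame(
        {
            "feature_id": [f"feat{j + 1}" for j in range(n_features)],
            "chrom": (np.arange(n_features) % 22 + 1).astype(str),
            "pos": np.arange(1, n_features + 1) * 500,
            "gene": [f"GENE{j + 1}" for j in range(n_features)],
        }
    )
    mats, phenos = [], []
    offset = 0
    for s, n in enumerate(samples_per_site):
        group = np.zeros(n, dtype=float)
        group[n // 2 :] = 1.0
        mu = mu0[:, None] * 2.0 ** (lfc[:, None] * group[None, :])
        if kind == "counts":
            # NB via gamma-Poisson; dispersion is the NB alpha (var = mu + alpha mu^2)
            shape = 1.0 / dispersion
            lam = rng.gamma(shape, mu / shape)
            values = rng.poisson(lam).astype(float)
        elif kind == "methylation_beta":
            base_m = rng.uniform(-2.0, 2.0, size=n_features)  # logit-scale baseline
            m = base_m[:, None] + lfc[:, None] * group[None, :]
            mean_beta = 1.0 / (1.0 + 2.0 ** (-m))
            a = mean_beta * beta_precision
            b = (1.0 - mean_beta) * beta_precision
            values = rng.beta(a, b)
        else:
            raise ValueError(f"unknown kind {kind!r}")
        ids = [f"site{s + 1}_samp{offset + k + 1}" for k in range(n)]
        offset += n
        mats.append(FeatureMatrix(values, feats_meta.copy(), ids, value_kind=kind))
        phenos.append(PhenotypeTable(ids, group, pd.DataFrame()))
    return mats, phenos, de_mask
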