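"""Study-level combination statistics and meta-level QC diagnostics.

Fisher's method (sum of logs) combines per-study p-values; the
inverse-variance-weighted (IVW) fixed-effect estimator combines per-study
effect sizes.  The QC diagnostics reproduce the standard summary-
statistics checks: EAF-vs-reference scatter (harmonization problems,
e.g. strand flips), P–Z consistency (reported p vs p recomputed from
beta/se), SE–N (trait-transformation problems: 1/median(se) should be
proportional to sqrt(n) across studies on a common trait scale), λ–N
(population stratification), plus Manhattan/QQ plot data and the genomic
inflation factor λ.  All plot-data operations are pure and return plain
tables; no plotting backend is needed to test them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StudySummary",
    "CombinedResult",
    "fisher_combine",
    "ivw_combine",
    "lambda_gc",
    "adjust_pvalues",
    "eaf_plot_data",
    "pz_plot_data",
    "se_n_plot_data",
    "lambda_n_plot_data",
    "manhattan_data",
    "qq_data",
    "read_sumstats",
    "write_sumstats",
]

SUMSTAT_COLUMNS = ["variant_id", "chrom", "pos", "EAF", "n", "beta", "se", "p"]


@dataclass
class StudySummary:
    """Per-study association summary statistics.

    ``table`` holds one row per variant/feature with columns
    variant_id, chrom, pos, EAF, n, beta, se, p (the toolkit's standard
    summary-statistics layout).
    """

    study_id: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"beta", "se", "p"} - set(self.table.columns)
        if missing:
            raise ValueError(f"study {self.study_id!r} missing columns {missing}")
        ok = self.table.dropna(subset=["se", "p"])
        if np.any(ok["se"] <= 0):
            raise ValueError("standard errors must be positive")
        if np.any((ok["p"] <= 0) | (ok["p"] > 1)):
            raise ValueError("p-values must lie in (0, 1]")

    @property
    def median_se(self) -> float:
        return float(self.table["se"].median())

    @property
    def n_max(self) -> float:
        return float(self.table["n"].max())

    @property
    def lambda_gc(self) -> float:
        return lambda_gc(self.table["p"].dropna().to_numpy())


@dataclass
class CombinedResult:
    """Result of combining k studies (Fisher or IVW)."""

    p: float
    k: int
    statistic: float | None = None  # Fisher chi-square
    df: int | None = None  # Fisher degrees of freedom (2k)
    beta: float | None = None  # IVW combined effect
    se: float | None = None  # IVW combined standard error


def fisher_combine(pvalues: Sequence[float]) -> CombinedResult:
    """Fisher's sum-of-logs combination: X² = −2 Σ ln p ~ χ²(2k) under H0.

    Zero p-values (numerical underflow upstream) are clamped to the
    smallest positive float with a warning, since the statistic diverges
    at 0.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if np.any(p > 1) or np.any(p < 0):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        warnings.warn("p-value of 0 clamped to smallest positive float")
        p = np.maximum(p, np.finfo(float).tiny)
    x2 = -2.0 * np.sum(np.log(p))
    df = 2 * p.size
    return CombinedResult(
        p=float(stats.chi2.sf(x2, df)), k=p.size, statistic=float(x2), df=df
    )


def ivw_combine(betas: Sequence[float], ses: Sequence[float]) -> CombinedResult:
    """Fixed-effect inverse-variance-weighted combination.

    Weights w_i = 1/se_i²; combined β = Σ wᵢβᵢ / Σ wᵢ with
    se = sqrt(1/Σ wᵢ) and a two-sided normal p-value.
    """
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.size == 0 or b.shape != s.shape:
        raise ValueError("need matching, non-empty beta and se vectors")
    if np.any(s <= 0):
        raise ValueError("standard errors must be positive")
    w = 1.0 / s**2
    beta = float(np.sum(w * b) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    p = float(2.0 * stats.norm.sf(abs(beta / se)))
    return CombinedResult(p=p, k=b.size, beta=beta, se=se)


def lambda_gc(pvalues: Sequence[float]) -> float:
    """Genomic inflation factor λ = median(χ²₁(p)) / median(χ²₁).

    The null median of the 1-df chi-square is taken from the quantile
    function, not hard-coded.
    """
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no p-values")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))


def adjust_pvalues(
    pvalues: Sequence[float], method: Literal["bonferroni", "bh"] = "bh"
) -> np.ndarray:
    """Multiple-testing adjustment (Bonferroni or Benjamini–Hochberg).

    NaN entries are passed through as NaN and do not count toward the
    number of tests.
    """
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        sm_method = {"bonferroni": "bonferroni", "bh": "fdr_bh"}[method]
        out[ok] = multipletests(p[ok], method=sm_method)[1]
    return out


# ---------------------------------------------------------------------------
# QC plot data
# ---------------------------------------------------------------------------

def eaf_plot_data(
    study: StudySummary,
    reference: pd.DataFrame,
    flag_threshold: float = 0.2,
) -> pd.DataFrame:
    """Study-vs-reference effect-allele-frequency pairs with outlier flags.

    ``reference`` needs columns variant_id and frequency (e.g. a 1000G
    frequency table).  Pairs whose absolute frequency difference exceeds
    ``flag_threshold`` are flagged — the signature of strand flips or
    allele-coding mix-ups.
    """
    ref = reference.set_index("variant_id")["frequency"]
    tab = study.table.set_index("variant_id")
    common = tab.index.intersection(ref.index)
    if len(common) == 0:
        warnings.warn("study and reference share no variants")
        return pd.DataFrame(
            columns=["variant_id", "study_eaf", "reference_eaf", "diff", "flagged"]
        )
    out = pd.DataFrame(
        {
            "variant_id": common,
            "study_eaf": tab.loc[common, "EAF"].to_numpy(),
            "reference_eaf": ref.loc[common].to_numpy(),
        }
    )
    out["diff"] = out["study_eaf"] - out["reference_eaf"]
    out["flagged"] = out["diff"].abs() > flag_threshold
    return out


def pz_plot_data(
    study: StudySummary, flag_log10_tol: float = 0.5
) -> pd.DataFrame:
    """Reported p versus p recomputed from beta/se (2·Φ(−|β/se|)).

    Discrepancies beyond ``flag_log10_tol`` on the −log10 scale are
    flagged; they indicate corrupted p columns or mismatched effect and
    error estimates upstream.
    """
    tab = study.table.dropna(subset=["beta", "se", "p"])
    z = tab["beta"].to_numpy() / tab["se"].to_numpy()
    expected = 2.0 * stats.norm.sf(np.abs(z))
    reported = tab["p"].to_numpy()
    with np.errstate(divide="ignore"):
        delta = np.abs(np.log10(reported) - np.log10(expected))
    return pd.DataFrame(
        {
            "variant_id": tab["variant_id"].to_numpy()
            if "variant_id" in tab
            else np.arange(len(tab)),
            "reported_p": reported,
            "expected_p": expected,
            "flagged": delta > flag_log10_tol,
        }
    )


def se_n_plot_data(
    studies: Sequence[StudySummary], flag_rel_tol: float = 0.5
) -> pd.DataFrame:
    """Per-study (sqrt(n), 1/median(se)) with deviation from the
    through-origin fit.

    On a common trait scale these points are collinear through the
    origin; a study off the line by more than ``flag_rel_tol`` (relative)
    suggests a different outcome transformation or unit.
    With a single study no fit is attempted.
    """
    rows = [
        (s.study_id, np.sqrt(s.n_max), 1.0 / s.median_se) for s in studies
    ]
    out = pd.DataFrame(rows, columns=["study", "sqrt_n", "inv_median_se"])
    if len(out) >= 2:
        x = out["sqrt_n"].to_numpy()
        y = out["inv_median_se"].to_numpy()
        slope = float(np.sum(x * y) / np.sum(x**2))
        out["fitted"] = slope * x
        with np.errstate(divide="ignore", invalid="ignore"):
            out["flagged"] = np.abs(y - out["fitted"]) / out["fitted"] > flag_rel_tol
    else:
        out["fitted"] = np.nan
        out["flagged"] = False
    return out


def lambda_n_plot_data(
    studies: Sequence[StudySummary], flag_lambda: float = 1.1
) -> pd.DataFrame:
    """Per-study (n, genomic inflation λ) pairs; λ above ``flag_lambda``
    flags possible population stratification."""
    rows = [(s.study_id, s.n_max, s.lambda_gc) for s in studies]
    out = pd.DataFrame(rows, columns=["study", "n", "lambda"])
    out["flagged"] = out["lambda"] > flag_lambda
    return out


def manhattan_data(results: pd.DataFrame) -> pd.DataFrame:
    """Cumulative genome coordinate and −log10 p for a Manhattan plot.

    Chromosomes are laid out end to end in their order of appearance;
    within a single chromosome the cumulative coordinate equals the
    position.
    """
    tab = results.dropna(subset=["p"]).copy()
    offset = 0.0
    coords = np.empty(len(tab))
    chroms = tab["chrom"].astype(str).to_numpy()
    pos = tab["pos"].to_numpy(dtype=float)
    for chrom in pd.unique(chroms):
        m = chroms == chrom
        coords[m] = pos[m] + offset
        offset += pos[m].max()
    tab["genome_coord"] = coords
    tab["neg_log10_p"] = -np.log10(tab["p"].to_numpy(dtype=float))
    return tab[["variant_id", "chrom", "pos", "genome_coord", "neg_log10_p"]]


def qq_data(pvalues: Sequence[float]) -> pd.DataFrame:
    """Expected vs observed −log10 p quantiles; p sorted ascending."""
    p = np.sort(np.asarray(pvalues, dtype=float))
    p = p[np.isfinite(p)]
    n = p.size
    expected = (np.arange(1, n + 1) - 0.5) / n
    return pd.DataFrame(
        {
            "p": p,
            "expected_neg_log10": -np.log10(expected),
            "observed_neg_log10": -np.log10(p),
        }
    )


def write_sumstats(table: pd.DataFrame, path) -> None:
    """Write a summary-statistics table (tab-delimited, with header)."""
    table.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_sumstats(path) -> pd.DataFrame:
    """Read a tab-delimited summary-statistics table."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    missing = set(SUMSTAT_COLUMNS[3:]) - set(df.columns)
    if missing:
        raise ValueError(f"summary statistics missing columns {sorted(missing)}")
    return df
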