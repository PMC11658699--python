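"""Epsilon-differential-privacy machinery and disclosure predicates.

The Laplace mechanism perturbs an aggregate f(D) with iid noise of scale
b = Δf/ε, where the sensitivity Δf = max ||f(D1) − f(D2)||₁ is taken over
dataset pairs differing in one individual.  For aggregates whose
sensitivity has no convenient closed form, Δf is estimated by resampling
leave-one-out pairs ("random differential privacy"): the guarantee then
holds except with a small probability γ.

The module also provides the two reusable disclosure predicates used by
the federation gate: cell suppression (block aggregates built from
non-empty groups smaller than a minimum cell size) and the MAF filter
(mask outputs for variants whose minor-allele frequency falls below a
threshold).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "SensitivityEstimate",
    "DPNoiseSpec",
    "laplace_mechanism",
    "estimate_sensitivity_resampling",
    "maf_gate",
    "cell_suppression_gate",
]


@dataclass(frozen=True)
class SensitivityEstimate:
    """Resampling estimate of the sensitivity Δf of an aggregate.

    Attributes
    ----------
    delta_f
        Estimated ℓ1 sensitivity (max over resampled leave-one-out pairs).
    n_resamples_used
        Number of resampling rounds N actually performed.
    gamma
        Probability that the privacy loss may exceed ε under the random-DP
        guarantee; recorded as metadata, not used in the computation.
    """

    delta_f: float
    n_resamples_used: int
    gamma: float

    def __post_init__(self) -> None:
        if self.delta_f < 0:
            raise ValueError("sensitivity must be nonnegative")
        if self.n_resamples_used < 1:
            raise ValueError("n_resamples_used must be positive")


@dataclass(frozen=True)
class DPNoiseSpec:
    """Scale of the Laplace noise applied to one aggregate: b = Δf/ε."""

    epsilon: float
    delta_f: float
    mechanism: str = "laplace"

    @property
    def scale(self) -> float:
        return self.delta_f / self.epsilon

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.delta_f < 0:
            raise ValueError("sensitivity must be nonnegative")


def laplace_mechanism(
    value: np.ndarray | float,
    sensitivity: float,
    epsilon: float,
    rng: np.random.Generator,
) -> np.ndarray | float:
    """Perturb ``value`` with iid Laplace(0, sensitivity/epsilon) noise.

    With ``sensitivity == 0`` the output is exactly the input (the
    zero-scale Laplace distribution is a point mass), so a disabled or
    trivially non-disclosive aggregate passes through bit-identical.

    Parameters
    ----------
    value
        Scalar or array aggregate to be released.
    sensitivity
        ℓ1 sensitivity Δf of the aggregate (per entry for arrays).
    epsilon
        Privacy parameter ε > 0; smaller means more privacy.
    rng
        Seeded :class:`numpy.random.Generator`; fixing the seed makes
        the release reproducible.
    """
    if epsilon <= 0:
        raise ValueError(f"invalid privacy parameter epsilon={epsilon!r}; must be > 0")
    if sensitivity < 0:
        raise ValueError("sensitivity must be nonnegative")
    arr = np.asarray(value, dtype=float)
    if sensitivity == 0:
        return arr.item() if np.isscalar(value) or arr.ndim == 0 else arr.copy()
    noise = rng.laplace(loc=0.0, scale=sensitivity / epsilon, size=arr.shape)
    out = arr + noise
    return out.item() if np.isscalar(value) or arr.ndim == 0 else out


def estimate_sensitivity_resampling(
    fn: Callable[[Sequence], np.ndarray | float],
    data: Sequence,
    n_resamples: int,
    rng: np.random.Generator,
    gamma: float = 0.1,
) -> SensitivityEstimate:
    """Estimate Δf by resampling leave-one-out dataset pairs.

    Each round draws two datasets D1, D2 from D, each missing one
    individual chosen uniformly at random (independently, so the two may
    coincide; a coinciding round contributes 0), evaluates
    ``||fn(D1) − fn(D2)||₁`` and keeps the maximum over ``n_resamples``
    rounds.  The estimate never exceeds — and converges to, as N grows —
    the exhaustive leave-one-out maximum.

    ``data`` is indexed along its first axis: a list of records or an
    array with one row per individual.
    """
    n = len(data)
    if n < 3:
        raise ValueError(
            f"dataset has {n} records; need at least 3 so two distinct "
            "leave-one-out subsets exist"
        )
    if n_resamples < 1:
        raise ValueError("n_resamples must be positive")
    is_array = isinstance(data, np.ndarray)

    def drop(idx: int):
        if is_array:
            return np.delete(data, idx, axis=0)
        return [rec for k, rec in enumerate(data) if k != idx]

    delta = 0.0
    for _ in range(n_resamples):
        i = int(rng.integers(n))
        j = int(rng.integers(n))
        f1 = np.asarray(fn(drop(i)), dtype=float)
        f2 = np.asarray(fn(drop(j)), dtype=float)
        if not (np.all(np.isfinite(f1)) and np.all(np.isfinite(f2))):
            raise ValueError("aggregate returned non-finite values on a resample")
        delta = max(delta, float(np.sum(np.abs(f1 - f2))))
    return SensitivityEstimate(delta_f=delta, n_resamples_used=n_resamples, gamma=gamma)


def maf_gate(maf: np.ndarray | float, threshold: float) -> np.ndarray:
    """Boolean mask: True where the MAF passes the disclosure filter.

    An entry passes iff ``maf >= threshold`` (strictly-below blocks, so
    the boundary value passes).  Missing MAFs (NaN) block.
    """
    if not 0 <= threshold <= 0.5:
        raise ValueError("MAF threshold must lie in [0, 0.5]")
    arr = np.atleast_1d(np.asarray(maf, dtype=float))
    if np.nanmax(arr, initial=0.0) > 0.5 + 1e-12 or np.nanmin(arr, initial=0.0) < 0:
        raise ValueError("MAF values must lie in [0, 0.5]")
    with np.errstate(invalid="ignore"):
        return arr >= threshold


def cell_suppression_gate(cell_counts: Sequence[int], min_cell_size: int) -> bool:
    """True (pass) unless any non-empty cell is smaller than ``min_cell_size``.

    Counts of exactly zero pass: an empty cell discloses nothing about
    any individual, whereas a small non-empty cell pins the aggregate to
    few people.
    """
    if min_cell_size < 1:
        raise ValueError("min_cell_size must be >= 1")
    counts = np.asarray(cell_counts)
    if np.any(counts < 0):
        raise ValueError("cell counts must be nonnegative")
    return not bool(np.any((counts > 0) & (counts < min_cell_size)))
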