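"""Simulated client / data-processor federation.

A :class:`FederationSession` holds an ordered list of
:class:`DataProcessor` sites.  Each site keeps its own data and its own
:class:`PrivacyConfig` — disclosure controls are configured per site, not
globally.  Every aggregate a site returns to the client passes through
:func:`gated_aggregate`, which applies, in order:

1. cell suppression — block if any non-empty group is smaller than the
   minimum cell size;
2. the MAF filter — mask entries for variants whose minor-allele
   frequency is below the site threshold;
3. Laplace differential-privacy noise (when enabled).

Suppression and masking run before noising so that blocking decisions are
never made on perturbed values.  Each site-touching operation appends one
audit record per site; the audit log is append-only and queryable.

Per-individual vectors (residuals, fitted values, PRS, PCA sample
scores) live in each site's ``server_side_store`` and are never included
in any value returned to the client.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Any, Literal, Sequence

import numpy as np

from fedomics.data import FeatureMatrix, GenotypeBlock, PhenotypeTable
from fedomics.privacy import cell_suppression_gate, laplace_mechanism, maf_gate

__all__ = [
    "PrivacyConfig",
    "AuditRecord",
    "DataProcessor",
    "FederationSession",
    "GateResult",
    "create_session",
    "gated_aggregate",
    "query_audit",
]

_record_counter = itertools.count()


@dataclass(frozen=True)
class PrivacyConfig:
    """Per-site disclosure controls.

    Defaults follow the all-filters-on convention: ε = 3, γ = 0.1,
    3 sensitivity resamples, MAF threshold 0.05 and a minimum cell size
    of 5 (the usual federated-analysis suppression default).
    """

    epsilon: float = 3.0
    gamma: float = 0.1
    n_resamples: int = 3
    maf_threshold: float = 0.05
    min_cell_size: int = 5
    dp_enabled: bool = True

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if not 0 < self.gamma < 1:
            raise ValueError("gamma must lie in (0, 1)")
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be positive")
        if not 0 <= self.maf_threshold <= 0.5:
            raise ValueError("maf_threshold must lie in [0, 0.5]")
        if self.min_cell_size < 1:
            raise ValueError("min_cell_size must be >= 1")


@dataclass(frozen=True)
class AuditRecord:
    timestamp: str
    user_id: str
    operation: str
    site_id: str
    parameter_digest: str
    outcome: str  # "passed" or "blocked:<gate>"
    dp_applied: bool
    sequence: int = field(default_factory=lambda: next(_record_counter))


@dataclass
class DataProcessor:
    """One study server: local data plus local disclosure configuration.

    ``server_side_store`` maps names to per-individual vectors (PRS,
    residuals, PCA scores).  Store contents never leave the site.
    """

    site_id: str
    genotype: GenotypeBlock | None = None
    phenotypes: PhenotypeTable | None = None
    features: FeatureMatrix | None = None
    config: PrivacyConfig = field(default_factory=PrivacyConfig)
    server_side_store: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = None
        for obj in (self.genotype, self.phenotypes, self.features):
            if obj is None:
                continue
            if ids is None:
                ids = list(obj.sample_ids)
            elif list(obj.sample_ids) != ids:
                raise ValueError(
                    f"site {self.site_id!r}: sample identifiers are inconsistent "
                    "across genotype/phenotype/feature data"
                )

    @property
    def n_samples(self) -> int:
        for obj in (self.genotype, self.phenotypes, self.features):
            if obj is not None:
                return obj.n_samples
        return 0


@dataclass
class FederationSession:
    """Client handle over the registered data processors."""

    processors: list[DataProcessor]
    user_id: str = "researcher"
    audit_log: list[AuditRecord] = field(default_factory=list)
    rng: np.random.Generator = field(default_factory=np.random.default_rng)

    def __post_init__(self) -> None:
        if not self.processors:
            raise ValueError("a session needs at least one data processor")
        ids = [p.site_id for p in self.processors]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate site ids: {ids}")

    @property
    def site_ids(self) -> list[str]:
        return [p.site_id for p in self.processors]

    def processor(self, site_id: str) -> DataProcessor:
        for p in self.processors:
            if p.site_id == site_id:
                return p
        raise KeyError(f"unknown site {site_id!r}")


@dataclass
class GateResult:
    """Outcome of one gated aggregate release.

    ``value`` is the (possibly noised, possibly entry-masked) aggregate,
    or None when the release was blocked outright.  Masked vector entries
    are returned as NaN.  Blocking is a result, not an error.
    """

    value: np.ndarray | float | None
    blocked: bool
    reason: str | None = None
    mask: np.ndarray | None = None  # True where an entry passed the MAF gate
    dp_applied: bool = False

    @property
    def passed(self) -> bool:
        return not self.blocked


def create_session(
    site_data: Sequence[
        tuple[
            GenotypeBlock | None,
            PhenotypeTable | None,
            FeatureMatrix | None,
            PrivacyConfig,
        ]
    ],
    user_id: str = "researcher",
    site_ids: Sequence[str] | None = None,
    seed: int | None = None,
) -> FederationSession:
    """Register per-site data and configs and open a session.

    Each tuple is ``(genotype, phenotypes, features, config)``; any data
    slot may be None.  Site ids default to ``site1..siteN``.  The seed
    drives all differential-privacy noise drawn during the session.
    """
    if site_ids is None:
        site_ids = [f"site{i + 1}" for i in range(len(site_data))]
    processors = [
        DataProcessor(site_id=sid, genotype=g, phenotypes=ph, features=fe, config=cfg)
        for sid, (g, ph, fe, cfg) in zip(site_ids, site_data, strict=True)
    ]
    return FederationSession(
        processors=processors, user_id=user_id, rng=np.random.default_rng(seed)
    )


def _digest(context: dict[str, Any]) -> str:
    keys = sorted(k for k in context if k != "mafs" and k != "cell_counts")
    payload = repr([(k, context[k]) for k in keys]).encode()
    return hashlib.sha1(payload).hexdigest()[:12]


def gated_aggregate(
    session: FederationSession,
    site_id: str,
    value: np.ndarray | float,
    context: dict[str, Any],
    operation: str = "aggregate",
) -> GateResult:
    """Pass a site aggregate through the disclosure gate.

    ``context`` carries what the gate needs:

    - ``kind``: "count" | "frequency" | "statistic" (audit metadata);
    - ``cell_counts``: group sizes feeding the suppression check;
    - ``mafs``: per-entry minor-allele frequencies for the MAF filter
      (vector aggregates are masked per entry; a scalar aggregate whose
      MAF fails blocks outright);
    - ``sensitivity``: ℓ1 sensitivity for the Laplace mechanism (scalar,
      or per-entry vector).

    Order is fixed: suppression, then MAF mask, then DP noise.
    """
    proc = session.processor(site_id)
    cfg = proc.config
    scalar = np.isscalar(value) or np.asarray(value).ndim == 0
    arr = np.atleast_1d(np.asarray(value, dtype=float)).copy()

    def _record(outcome: str, dp_applied: bool) -> None:
        session.audit_log.append(
            AuditRecord(
                timestamp=datetime.now(timezone.utc).isoformat(),
                user_id=session.user_id,
                operation=operation,
                site_id=site_id,
                parameter_digest=_digest(context),
                outcome=outcome,
                dp_applied=dp_applied,
            )
        )

    # 1. cell suppression (all-or-nothing)
    cell_counts = context.get("cell_counts")
    if cell_counts is not None and not cell_suppression_gate(
        cell_counts, cfg.min_cell_size
    ):
        _record("blocked:cell_suppression", False)
        return GateResult(value=None, blocked=True, reason="cell_suppression")

    # 2. MAF filter (per-entry for vectors, all-or-nothing for scalars)
    mask = None
    mafs = context.get("mafs")
    if mafs is not None:
        mask = maf_gate(np.asarray(mafs, dtype=float), cfg.maf_threshold)
        if scalar:
            if not bool(np.all(mask)):
                _record("blocked:maf_filter", False)
                return GateResult(value=None, blocked=True, reason="maf_filter")
        else:
            if mask.shape != arr.shape:
                raise ValueError("mafs must match the aggregate's shape")
            arr[~mask] = np.nan

    # 3. Laplace noise
    dp_applied = False
    if cfg.dp_enabled:
        sens = np.asarray(context.get("sensitivity", 0.0), dtype=float)
        if np.any(sens > 0):
            noise = session.rng.laplace(0.0, 1.0, size=arr.shape)
            arr = arr + noise * np.broadcast_to(sens / cfg.epsilon, arr.shape)
            dp_applied = True
        else:
            # zero sensitivity: mechanism degenerates to the identity
            arr = laplace_mechanism(arr, 0.0, cfg.epsilon, session.rng)
    _record("passed", dp_applied)
    out = arr.item() if scalar else arr
    return GateResult(value=out, blocked=False, mask=mask, dp_applied=dp_applied)


def query_audit(
    session: FederationSession,
    user: str | None = None,
    operation: str | None = None,
    outcome: Literal["passed", "blocked"] | None = None,
) -> list[AuditRecord]:
    """Return matching audit records in insertion order."""
    out = []
    for rec in session.audit_log:
        if user is not None and rec.user_id != user:
            continue
        if operation is not None and rec.operation != operation:
            continue
        if outcome is not None and not rec.outcome.startswith(outcome):
            continue
        out.append(rec)
    return out
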