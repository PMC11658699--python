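"""Federation configuration files.

A YAML config describes the sites of a federation: data file paths and
per-site disclosure controls.  Schema::

    user_id: researcher            # optional
    seed: 1                        # optional; drives DP noise
    sites:
      - site_id: cohort_a
        dosage_matrix: a.dosages.tsv     # or: vcf: a.vcf
        phenotypes: a.pheno.tsv          # optional
        features: a.features.tsv         # optional
        feature_kind: counts             # counts|methylation_beta|continuous
        privacy:                         # all keys optional
          epsilon: 3.0
          gamma: 0.1
          n_resamples: 3
          maf_threshold: 0.05
          min_cell_size: 5
          dp_enabled: true

Relative data paths resolve against the config file's directory.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from fedomics.data import (
    read_dosage_matrix,
    read_feature_matrix,
    read_phenotypes,
    read_vcf,
)
from fedomics.federation import FederationSession, PrivacyConfig, create_session

__all__ = ["load_session", "load_config"]


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "sites" not in cfg or not cfg["sites"]:
        raise ValueError(f"{path}: config must define at least one site")
    return cfg


def load_session(path: str | Path, seed: int | None = None) -> FederationSession:
    """Build a :class:`FederationSession` from a YAML config file."""
    path = Path(path)
    cfg = load_config(path)
    base = path.parent
    site_data, site_ids = [], []
    for i, site in enumerate(cfg["sites"]):
        site_ids.append(str(site.get("site_id", f"site{i + 1}")))
        geno = None
        if "dosage_matrix" in site:
            geno = read_dosage_matrix(base / site["dosage_matrix"])
        elif "vcf" in site:
            geno, _ = read_vcf(base / site["vcf"])
        pheno = (
            read_phenotypes(base / site["phenotypes"])
            if "phenotypes" in site
            else None
        )
        feats = (
            read_feature_matrix(
                base / site["features"],
                value_kind=site.get("feature_kind", "continuous"),
            )
            if "features" in site
            else None
        )
        privacy = PrivacyConfig(**(site.get("privacy") or {}))
        site_data.append((geno, pheno, feats, privacy))
    if seed is None:
        seed = cfg.get("seed")
    return create_session(
        site_data,
        user_id=str(cfg.get("user_id", "researcher")),
        site_ids=site_ids,
        seed=seed,
    )
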