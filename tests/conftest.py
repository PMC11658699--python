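import numpy as np
import pandas as pd
import pytest

from fedomics import (
    GenotypeBlock,
    PhenotypeTable,
    PrivacyConfig,
    create_session,
    simulate_genotypes,
    simulate_phenotype,
)

# gates disabled: used wherever federated/single-machine equivalence is asserted
OPEN = PrivacyConfig(dp_enabled=False, maf_threshold=0.0, min_cell_size=1)


def make_block(dosages, sample_prefix="s", variant_prefix="rs", ref="A", alt="G"):
    dosages = np.asarray(dosages, dtype=float)
    m, n = dosages.shape
    variants = pd.DataFrame(
        {
            "variant_id": [f"{variant_prefix}{j + 1}" for j in range(m)],
            "chrom": "1",
            "pos": np.arange(1, m + 1) * 100,
            "ref": ref,
            "alt": alt,
        }
    )
    return GenotypeBlock(dosages, variants, [f"{sample_prefix}{i}" for i in range(n)])


@pytest.fixture
def two_site_session():
    """Two sites, 60 samples each, 30 variants, gaussian phenotype, gates off."""
    blocks = simulate_genotypes(2, 60, 30, fst=0.02, seed=11)
    phenos = simulate_phenotype(
        blocks, covariate_effects={"age": 0.2}, noise_sd=1.0, seed=12
    )
    return create_session(
        [(b, p, None, OPEN) for b, p in zip(blocks, phenos)], seed=13
    )


@pytest.fixture
def concatenated(two_site_session):
    blocks = [p.genotype for p in two_site_session.processors]
    phenos = [p.phenotypes for p in two_site_session.processors]
    G = np.hstack([b.dosages for b in blocks])
    y = np.concatenate([p.outcome for p in phenos])
    X = np.column_stack(
        [np.ones(len(y)), np.concatenate([p.covariates["age"] for p in phenos])]
    )
    return G, y, X


def make_session_from_dosages(per_site_dosages, config=OPEN, phenotypes=None, seed=0):
    blocks = []
    offset = 0
    for d in per_site_dosages:
        d = np.asarray(d, dtype=float)
        blocks.append(make_block(d, sample_prefix=f"s{offset}_"))
        offset += 1
    site_data = []
    for i, b in enumerate(blocks):
        ph = None
        if phenotypes is not None:
            ph = PhenotypeTable(list(b.sample_ids), np.asarray(phenotypes[i], float))
        site_data.append((b, ph, None, config))
    return create_session(site_data, seed=seed)
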