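# fedomics

Federated, privacy-protected analysis of multi-cohort omics data.

Consortia that hold genotype, gene-expression or DNA-methylation data at
separate sites often cannot move individual-level records across
institutional or national boundaries. `fedomics` simulates the
client/data-processor topology used by federated analysis platforms:
each site (data processor) keeps its data and its own disclosure
configuration, the client sends computations to the sites, and **every
aggregate returned to the client passes a disclosure gate** — cell
suppression, a minor-allele-frequency (MAF) filter, and Laplace
differential-privacy noise — with every release written to an audit log.

On top of that federation the package implements the standard
genomic/omic toolchain in two designs:

- **virtually pooled ("mega") analysis** — federated algebra engineered
  so the result equals the single-machine analysis of all data
  concatenated;
- **meta-analysis** — per-site summary statistics combined by
  inverse-variance weighting (effect sizes) or Fisher's method
  (p-values), with the usual meta-level QC diagnostics.

## Methods at the core

**Fast virtually pooled GWAS.** Fit the covariate-only null model
y ~ covariates once by federated IRLS; each site keeps its fitted values
and residuals. With centred residuals `yc` and 0/1/2 dosages `g`, each
site returns only four gated per-variant sums, B = Σ yc·g, S1 = Σ g,
S2 = Σ g², YC2 = Σ yc², and the client computes

    DEN1 = S2 − S1²/N        β  = B / DEN1
    σ    = (YC2 − β²·DEN1) / (N − K − 2)
    SE   = √(σ / DEN1)       p  = 2·Φ(−|β/SE|)

which reproduces per-variant OLS of the null residuals on dosage — one
pass over the genotype matrix instead of a GLM per variant.

**ε-differential privacy.** Released aggregates f(D) are perturbed with
Laplace(0, Δf/ε) noise, where the sensitivity Δf = max‖f(D₁)−f(D₂)‖₁ is
either a closed-form bound (possible for bounded 0/1/2 dosage sums) or
estimated by resampling leave-one-out dataset pairs (random differential
privacy, with risk parameter γ). Defaults: ε = 3, γ = 0.1, 3 resamples,
MAF threshold 0.05, minimum cell size 5 — all configurable per site.

**Pooled PCA by block SVD.** Sites standardize dosages to
(X − 2pⱼ)/√(2pⱼ(1−pⱼ)) with pooled frequencies, SVD locally and share
only uᵢ·diag(dᵢ) (variants × rank — no per-sample columns, so site data
are not reconstructible). The client SVDs the horizontal concatenation
of the shares; its singular values equal those of the concatenated
matrix exactly, and sites project their own samples server-side.

**PRS.** PRSᵢ = Σⱼ Xᵢⱼβⱼ with scorefile/genotype allele harmonization
(dosage reflected to 2−X when the effect allele is the reference
allele). Scores are per-individual and therefore disclosive: they stay
on the servers, usable as covariates later; the client sees only a
completion summary.

**DGE / EWAS.** Log2-CPM (counts) or M-value (methylation) per-feature
OLS per site, pooled exactly via gated cross-product aggregates or
combined by Fisher's method, with Benjamini–Hochberg or Bonferroni
adjustment; CPM-based low-count filtering and winsorization included.

A synthetic-data module generates everything the analyses consume —
Balding–Nichols structured genotypes, GLM phenotypes, negative-binomial
counts, Beta-distributed methylation — so no downloads are required.

## Worked example

```python
import numpy as np
from fedomics import (PrivacyConfig, create_session, simulate_genotypes,
                      simulate_phenotype, fit_null_glm, fast_pooled_gwas,
                      query_audit)

# three cohorts that never share individual-level data
blocks = simulate_genotypes(n_sites=3, samples_per_site=200, n_variants=500,
                            fst=0.01, seed=7)
phenos = simulate_phenotype(blocks, causal=[("rs42", 0.5)],
                            covariate_effects={"age": 0.2}, seed=8)
cfg = PrivacyConfig(epsilon=3.0, maf_threshold=0.05, dp_enabled=False)
session = create_session([(b, p, None, cfg) for b, p in zip(blocks, phenos)],
                         seed=9)

null = fit_null_glm(session, "outcome ~ age")
scan = fast_pooled_gwas(session, null)
print(scan.nsmallest(3, "p")[["variant_id", "EAF", "n", "beta", "se", "p"]]
      .to_string(index=False))
print(f"audit records: {len(query_audit(session))}")
```

```
variant_id   EAF     n      beta       se            p
      rs42 0.420 600.0  0.473734 0.058074 3.420680e-16
      rs24 0.095 600.0 -0.306695 0.105232 3.563127e-03
     rs113 0.130 600.0 -0.220270 0.086653 1.102230e-02
audit records: 24
```

The simulated causal variant `rs42` (true effect 0.5) is the top hit
with its estimate within one standard error of the truth; the audit log
holds one record per site per gated aggregate release (8 releases × 3
sites). Setting `dp_enabled=True` adds seeded Laplace noise to every
release; lowering `maf_threshold`/`min_cell_size` relaxes the masking.

The same analyses are available from the shell:

```sh
fedomics simulate --out-dir demo --sites 3 --samples 200 --variants 500 --seed 7
fedomics gwas --config demo/config.yaml --formula "outcome ~ age" --out gwas.tsv
fedomics pca --config demo/config.yaml -k 5 --out pca.tsv
```

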