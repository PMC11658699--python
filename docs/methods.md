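# Methods

This note documents the statistical machinery behind `fedomics`: the
federation and disclosure model, the pooled and meta estimators, the
differential-privacy mechanism, the synthetic-data generators, and the
numerical and design choices made where the literature leaves the
details open.

## Federation and disclosure model

A session is an ordered list of data processors (sites). Each site
holds its genotype block (variants × samples, 0/1/2 alternate-allele
dosages, NaN missing), phenotype table, and/or feature matrix, plus a
`PrivacyConfig` of its own — disclosure controls are a per-site policy,
not a global one. All transport is in-process; networking, TLS and user
management are deployment concerns outside this package's scope.

Every site-to-client aggregate passes `gated_aggregate`, which applies,
in this fixed order:

1. **cell suppression** — block the release outright if any *non-empty*
   group feeding the aggregate has fewer than `min_cell_size` members
   (default 5, the common federated-analysis convention). Empty cells
   pass: a count of zero pins down no individual.
2. **MAF filter** — mask entries whose minor-allele frequency is below
   `maf_threshold` (default 0.05). The boundary passes ("lower than"
   blocks strictly below). Vector aggregates are masked per entry
   (masked entries return as NaN); a scalar aggregate failing the
   filter blocks outright.
3. **Laplace noise** — when `dp_enabled`, add iid Laplace(0, Δf/ε)
   noise per entry.

Suppression and masking run before noising so blocking decisions are
never made on perturbed values. Each release appends one audit record
per site (user, operation, parameter digest, gate outcome, whether
noise was applied); the log is append-only and queryable. Per-individual
vectors (null-model residuals and fitted values, PCA sample scores,
polygenic scores) live in a per-site `server_side_store` and are never
part of a returned payload.

The toolkit logs every gate decision but does not budget ε across
queries; repeated querying is visible in the audit trail, not prevented.
This mirrors current federated-analysis practice and is a known
limitation.

## Differential privacy

The Laplace mechanism releases f(D) + Laplace(0, b)ⁿ with scale
b = Δf/ε, where Δf = max‖f(D₁)−f(D₂)‖₁ over dataset pairs differing in
one individual. The ε-DP inequality
Pr[A(D₁)∈S] ≤ exp(ε)·Pr[A(D₂)∈S] follows from the density ratio of the
two shifted Laplace distributions, which the test suite checks in
closed form. Zero sensitivity degenerates to the identity, so disabled
or trivially non-disclosive releases are bit-exact.

For aggregates without a convenient closed form, Δf is estimated by
resampling: N times, draw D₁ and D₂ from D each missing one uniformly
chosen individual (drawn independently — the two may coincide, and a
coinciding round contributes 0, matching the procedure's literal
definition), and keep the maximum ℓ1 difference of the aggregate. The
estimate never exceeds the exhaustive leave-one-out maximum and reaches
it with probability → 1 in N. This is *random* differential privacy:
the guarantee holds except with probability γ. The mapping from γ to a
required N involves a bound we do not reproduce from its source; the
default is the fixed resample count from the site config (3), with γ
(default 0.1) carried as metadata. The resample-count strategy is a
plain argument, so a calibrated rule can be plugged in.

Where the aggregate is a sum of bounded 0/1/2 dosages, closed-form
sensitivities are used instead of resampling: per variant, one
individual changes Σg by at most 2, Σg² by at most 4, Σ yc·g by at most
2·max|yc| and Σ yc² by at most max(yc²), using the site's residual
range as the bound on |yc|.

Which intermediate aggregates receive noise, per pipeline: allele
frequency — the per-variant allele counts and allele numbers;
fast GWAS — the four per-variant sums and the residual-sum used for
pooled centring; federated IRLS — the per-iteration X'WX and X'Wz
(resampled sensitivity); per-SNP GLM and per-feature models — the
effect estimates (resampled sensitivity), with test statistics
recomputed from the noised effects; PCA — the site shares (resampled
sensitivity on the sign-aligned, rank-padded share). Exact Hardy–
Weinberg p-values pass suppression and the MAF mask but are not noised:
additive noise on a probability leaves [0,1] and would invalidate the
downstream Fisher combination. PRS releases nothing per-individual to
noise.

## Allele frequency and exact HWE

Each site returns per-variant (alternate-allele count, allele number)
with the allele number = 2 × non-missing samples; the client sums
counts across sites and divides by summed allele numbers, so missing
genotypes are excluded by construction. Sites whose MAF filter masks a
variant simply do not contribute to it; a variant masked everywhere is
reported missing.

The exact HWE test conditions on the observed minor-allele count and
enumerates all heterozygote counts of matching parity; table
probabilities are computed with log-gamma factorials and the p-value is
the total probability of tables no more likely than the observed one
(with a 1+1e−12 tie tolerance). Per-site p-values are combined across
sites by Fisher's method. The controls-only variant restricts to
samples with outcome 0, the usual GWAS-QC convention.

## Null model and the fast pooled scan

The covariate-only GLM (gaussian or binomial) is fitted by federated
IRLS: the client broadcasts coefficients, sites return gated X'WX and
X'Wz of the working response, the client solves, and iteration stops
when the largest coefficient change falls below 1e−8 (cap 25). With
noised aggregates that tolerance is unreachable — the iterates jitter
at the noise floor — so under DP the final capped iterate is released
with a warning rather than an error. After convergence each site stores
its fitted values and response-scale residuals server-side.

Residuals are centred by the *pooled* residual mean (one extra gated
scalar per site) rather than per site: pooled centring is the algebra
that reproduces the concatenated-data computation exactly, and since
GLM residuals have near-zero mean the difference is tiny either way;
per-site centring remains available as an option. The σ divisor is the
residual degrees of freedom N − K − 2 for intercept + K covariates +
dosage, and p-values use the normal approximation 2·Φ(−|β/SE|), not a
t reference — at GWAS sample sizes the difference is negligible.

Missing dosages are handled pairwise-complete per variant: all four
sums and the per-variant N count only non-missing samples. Monomorphic
variants (DEN1 ≤ 0) are reported missing. The MAF filter is applied to
the scan *output* — variants whose pooled MAF falls below the most
restrictive site threshold are masked — rather than by masking each
site's intermediate sums, which keeps the pooled estimator identical to
the concatenated computation for the variants that are reported.

For binomial outcomes the scan regresses response-scale residuals
(y − fitted probability) on dosage. This is an approximation to the
per-variant logistic GLM — exact only in the score-test limit — and is
validated on the synthetic benchmark, where the correlation between
scan betas and full logistic betas exceeds 0.999. The full per-SNP GLM
(`per_snp_glm`, statsmodels IRLS per site) is the non-approximate
route and feeds the inverse-variance meta-analysis.

## Pooled PCA

Dosages are standardized to (X − 2pⱼ)/√(2pⱼ(1−pⱼ)) — the mean and the
expected standard deviation under Hardy–Weinberg equilibrium — using
*pooled* frequencies (a per-site choice would make the site blocks
incomparable). Monomorphic variants are excluded with a report;
missing dosages become 0 after centring (mean imputation). An
ancestry-informative variant subset can be supplied; the analysis is
otherwise genome-wide.

Each site shares uᵢ·diag(dᵢ) from its local SVD, untruncated (full
local rank): since uᵢdᵢ = ZᵢVᵢ with Vᵢ orthonormal spanning the row
space, the horizontal concatenation of the shares has exactly the
singular values and left singular vectors of the concatenated
standardized matrix, so truncation to k components happens only after
pooling. Shares have shape variants × rank — never a per-sample
column. Loading signs are fixed by forcing the first non-negligible
entry of each column nonnegative, making results deterministic. Sites
project their own samples onto the pooled loadings and keep the scores
server-side, where they can be named as covariates in later formulas.

## PRS

Scores are matched by variant id; the scorefile's effect allele is
compared with the block's alternate (dosage used as-is) or reference
(dosage reflected to 2 − X) allele, and variants matching neither are
skipped and counted. Missing dosages contribute 0 to the sum. Because
the score is per-individual, the client receives only a completion
summary; the score vector is stored server-side under a user-chosen
name. Site partitioning cannot change a per-individual sum, and the
test suite asserts that invariance.

## DGE and EWAS

Counts are transformed to log2(CPM + 0.5), methylation beta-values to
M-values log2(β/(1−β)) with a 1e−6 clamp; both are standard
variance-stabilizing choices. Low-count filtering keeps features with
CPM > 1 in ≥ 50% of samples (defaults), federated as the intersection
of per-site keep-lists so all sites model identical features.
Winsorization clamps each feature at its tail quantiles (default 0.005
per tail) per site independently; it never moves a median.

Per-feature inference is ordinary least squares of the transformed
abundance on intercept + group + covariates, with t-based p-values at
the per-site (meta mode) or pooled (pooled mode) residual degrees of
freedom. Pooled mode transmits X'X, X'y per feature, y'y per feature
and n, and solves the pooled normal equations — exactly the
concatenated-sample OLS when DP is off; a site whose feature is
entirely missing drops out of that feature's aggregates. Meta mode
combines per-site p-values by Fisher's method and adjusts by
Benjamini–Hochberg or Bonferroni. Empirical-Bayes moderation,
dispersion modelling, TMM normalization and surrogate-variable
adjustment are deliberately out of scope — the contribution here is the
federated scaffold, not a new expression engine; surrogate variables in
particular require the centralised data matrix.

## Meta-level QC

Fisher: X² = −2Σln pᵢ ~ χ²(2k); zero p-values are clamped to the
smallest positive float with a warning. IVW: weights 1/se², combined
se = √(1/Σw). λ uses the χ²₁ median from the quantile function, not a
hard-coded constant. The diagnostics return plain tables: EAF-vs-
reference pairs flagged at |Δf| > 0.2; P–Z pairs flagged beyond 0.5 on
the −log10 scale (loose enough that a t-vs-normal discrepancy at n=30
does not flag); SE–N as (√n, 1/median se) with a through-origin fit
and a 50% relative-deviation flag; λ–N flagged above 1.1. The flag
thresholds are package defaults — the underlying QC protocol names the
plots but no cutoffs — and every threshold is an argument.

## Synthetic data

Genotypes follow the Balding–Nichols model: ancestral frequencies
uniform on (0.05, 0.5] by default, per-site frequencies
Beta(p(1−F)/F, (1−p)(1−F)/F) at divergence F (sites share p at F = 0),
genotypes Binomial(2, p_site) — Hardy–Weinberg within site, with the
realized F_ST matching the target across many variants. Phenotypes are
GLM-generated (gaussian noise or Bernoulli via inverse-logit) from
chosen causal dosages and standard-normal covariates. Counts are
gamma-Poisson (negative binomial, variance μ + αμ²) with log-normal
baseline means (median 100, log-sd 1) and dispersion α = 0.2; DE
features shift the group mean by ±LFC on the log2 scale, half up, half
down. Methylation betas are Beta-distributed with precision 30 and the
group shifting the logit-scale mean. All generators are deterministic
under a seed.

What the generators do *not* emulate: linkage disequilibrium (variants
are independent), genotyping error, batch effects, library-size
heterogeneity beyond sampling noise, correlated features, or
cell-type composition. Passing benchmarks therefore demonstrate the
correctness of the federated algebra and the calibration of the
statistics under clean sampling assumptions — not robustness to the
artefacts of real cohort data.

## Benchmark problem sizes

The validation scenarios use 3–4 sites with 50–200 samples each,
300–2000 variants, and 1000 features × 120 samples for expression —
sizes chosen so the full suite runs in seconds on one CPU while leaving
Monte-Carlo error well inside the asserted bands (e.g. ±0.01 on a
type-I error of 0.05 at 2000 tests, ≥ 90% joint success over 50
recovery replicates).

## Known limitations

- No ε-budget accounting across queries (audit-only).
- The binomial fast scan is an approximation; use `per_snp_glm` when
  exact per-variant logistic inference matters.
- Random-effects meta-analysis and heterogeneity statistics (Q, I²)
  are not provided.
- The PCA share under DP uses a resampled sensitivity of a
  sign-aligned, rank-padded share; SVD sign/rank instability can make
  this bound loose, and noised shares degrade components accordingly.
- Usability under aggressive privacy settings is dataset-specific; no
  universal "usable ε" constant is encoded.
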