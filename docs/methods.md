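# Methods

This note documents the statistical models behind `sczprio`, the defaults
and why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical conventions that matter for reproducing results.

## Problem setting

Genome-wide association studies of schizophrenia implicate loci, not genes:
most risk variants are non-coding and presumably act by changing expression.
The pipeline integrates GWAS summary statistics with brain eQTL tables to
score genes, then accumulates orthogonal evidence — protein–protein
interaction (PPI) connectivity with the GWAS-significant gene set,
co-expression with that set in brain region clusters, early-developmental
expression bias, and case–control differential expression — into a
convergent functional genomics (CFG) score per gene.

All association evidence lives on the standardized z scale (unit standard
error). A two-sided p and |z| are interchangeable (p = 2Φ(−|z|)); every
statistic downstream uses z² only, so a z recovered from a p-value with
unknown sign is lossless.

## Gene scoring by summed log Bayes factors

For a gene g, its eSNPs are the SNPs whose eQTL p-value falls below
`esnp_p_threshold` (default 1e-5; chosen so that all supporting eSNPs of
the kind reported in published tables, with eQTL p up to ~8e-6, qualify).
Each eSNP contributes an approximate log Bayes factor computed from its
GWAS z-score with a Normal(0, W) prior on the true standardized effect:

    LBF(z; W) = ½ ln(1/(1+W)) + (z²/2) · W/(1+W)

This is the Wakefield-style approximate Bayes factor for association
versus null given one summary statistic. It is strictly increasing in z²,
*negative* when the eSNP shows no disease association (at z = 0 it equals
½ ln(1/(1+W)) < 0), and crosses zero at z² = ((1+W)/W) ln(1+W). The gene
score is the sum over its eSNPs, and exp(total LBF) is the odds of
association versus the null (a total of 5.64 corresponds to 281-fold
odds). SNPs with GWAS signal but no eQTL association never enter any score.

The original published integration tool uses a richer hierarchical model
(multi-category priors, LD handling); this package deliberately implements
the minimal form above because it reproduces the documented qualitative
contract — positive scores for disease-associated eSNPs, negative
otherwise, summed per gene — with a single interpretable parameter.
**W defaults to 0.15**, a weakly informative prior spread for standardized
effects of complex-trait loci; it is configurable and results are
insensitive to it in rank terms (it rescales the z² term monotonically).

Gene-level significance is Monte-Carlo: a matched null gene has the same
number of eSNPs, each drawing GWAS z ~ N(0,1); the empirical p-value is
(1 + #{null total ≥ observed}) / (1 + n) with `n_null_draws_lbf = 10,000`
by default, so the resolution floor is ~1e-4. Bonferroni correction
multiplies by the number of genes tested (the same operation that turns a
family-wise 0.05 over 8,998 expression-tested genes into a per-gene
threshold of 5.6e-6). Inside `lbf_scan` the null sample is shared across
genes with equal eSNP counts, with the child seed derived from (scan seed,
eSNP count), making results independent of gene order; calibration
experiments use independent per-gene nulls.

## Summary-data Mendelian randomization

Per gene, the most significant *cis* eQTL below
`smr_instrument_p_threshold` (default 5e-8, the conventional genome-wide
line; trans records never instrument) serves as the instrument, and

    T_SMR = z_GWAS² · z_eQTL² / (z_GWAS² + z_eQTL²)

is referred to a 1-df chi-square upper tail. T_SMR is symmetric, invariant
to sign flips, bounded by min(z_GWAS², z_eQTL²), and approaches z_GWAS² as
the instrument strengthens; with a strong instrument the null rejection
rate at 0.05 is slightly conservative (≈0.0456 at z_eQTL = 10, because the
finite instrument shrinks the statistic). The HEIDI heterogeneity test is
out of scope. Bonferroni correction is over the genes that had an
instrument.

## Permutation tests of cross-set connectivity

The statistic is the number of network edges with one endpoint in the
candidate set and the other in the reference (GWAS-significant) set.
Edges internal to either set are excluded — candidate–candidate edges say
nothing about enrichment toward the reference — and a gene belonging to
both sets counts on the reference side. Permuted sets draw, without
replacement, as many genes as the candidate set has *measurable* members
(present in the graph or expression panel, mirroring how candidates
missing from a resource drop out of the observed statistic) from the
background universe with reference genes removed, so a permuted set can
never inflate its score by containing reference genes. The p-value is the
plain exceedance fraction k/n (not add-one), reported as "< 1/n" when
k = 0 — this matches the convention that produces reports like
"P < 1.0e-3" at n = 1,000. Default `n_permutations = 1000`.

Co-expression networks connect a gene pair when |Pearson r| > 0.8 over the
samples of one region cluster (four clusters: V1C-STC, PFC-MSC, STR-AMY,
MD-CBC; the region→cluster map is an input table). Correlations are taken
over all samples assigned to the cluster; averaging to donor level first
is a defensible alternative the package does not implement. Zero-variance
genes have undefined correlation and are excluded with a log message
rather than erroring, so flat genes cannot abort a batch run.

## Developmental expression pattern

Each gene's trajectory is min–max standardized, x → (x − min)/(max − min),
across all of that gene's samples (constant vectors map to zeros with a
warning). The early window is age ≤ `early_stage_max` and the late window
age ≥ `late_stage_min`; ages are post-conception days throughout, and the
defaults 386 and 3,186 correspond to 4 months after birth and 8 years
(birth ≈ 266 days), the bounds of the embryonic/fetal versus
childhood/adult comparison. Samples between the windows are ignored. The
gene-set statistic is the count of candidate genes whose early mean
*strictly* exceeds the late mean (ties and flat genes count as not
exceeding); permutation proceeds as above, drawing from the background
universe (candidates may be redrawn — the background is the comparison
population, not an exclusion list). The count statistic is one reading of
"same or more extreme expression pattern" for a permuted set; it was
chosen because it is integer-valued and admits an exact enumeration
oracle. It is exactly invariant under per-gene affine transforms with
positive slope, but not under arbitrary monotone transforms (the mean
comparison is not a rank statistic).

## Case–control differential expression

Classical pooled-variance two-sample Student t per gene and region
(`de_equal_var = False` switches to Welch), two-sided p, no multiple-
testing correction at this stage — the CFG layer consumes raw p-values
against `alpha`. Groups need ≥ 2 samples each and non-degenerate variance;
expression is tested on the scale provided (no log transform is applied).

## CFG scoring

Nine boolean channels, one point each, in fixed order: discovery LBF,
PPI, co-expression, differential expression, replication LBF (an
independent eQTL panel scored against the same GWAS), SMR, brain
structure, cognition, functional assay. The last three come from external
resources and are supplied as per-gene booleans (default false). Award
rules, configurable through `alpha` (default 0.05):

- discovery / replication / SMR: Bonferroni-corrected p < alpha;
- PPI / co-expression: the set-level permutation test significant *and*
  the gene itself contributing ≥ 1 cross edge (in ≥ 1 significant cluster
  for co-expression);
- differential expression: raw p < alpha in ≥ 1 region with a consistent
  direction across that gene's significant regions.

Ranking is by descending score, ties broken by descending total LBF, then
gene id. The published study did not print its exact per-channel criteria;
these rules are this package's documented operationalization.

## Synthetic data: what is and is not emulated

The generators are pure functions of their parameters and seed.

`gen_gwas_eqtl` plants risk genes whose eSNPs carry GWAS signal: every
gene receives a disjoint block of eSNPs with eQTL z ~ N(μ_eQTL, 1); GWAS z
is N(0,1) everywhere except the risk genes' eSNPs, which draw N(μ_GWAS, 1).
SNPs are independent — no LD — because the scoring model never uses LD.
Defaults in the end-to-end bundle: 1,000 SNPs, 100 genes, 3 risk genes,
5 eSNPs/gene, μ_GWAS = 5, μ_eQTL = 7 (a clearly-detectable planted regime).

`gen_expression_panel` builds a brain panel from a 12-donor developmental
series (7 donors at or before 4 months, 4 at or after 8 years) times a
configurable region set, plus adult case/control donors (defaults 19 + 19,
sampled in hippocampus, prefrontal cortex and striatum). Early-high genes
decline linearly in age between the windows by a factor `decay` of the
baseline; co-expression block genes share a per-sample latent factor with
loading λ, giving pairwise |r| ≈ λ²/(λ² + σ²) for flat genes; DE genes are
shifted in cases by `de_shift` with random sign. In the end-to-end bundle
the risk genes carry all three expression signals, and the block loading
defaults to 6.0 because the risk genes' decay trend (amplitude 7 units)
adds uncorrelated variance — a loading near 1 would leave risk–reference
correlations below the 0.8 edge threshold and the planted block would not
exist as such.

`gen_network` is an Erdős–Rényi background with cross-set pairs drawn at a
separate probability (a pair inside the A∩B overlap is assigned the cross
probability once).

Not emulated: allele frequencies, genomic coordinates, LD structure, real
BrainSpan region counts or donor ages, platform-specific expression
distributions, and network degree heterogeneity (the PPI background is
homogeneous, unlike scale-free interactomes). Passing tests therefore
demonstrate the statistical machinery — calibration under the null and
power against planted signal — not performance on real cohorts.

## Numerical conventions and degenerate inputs

- Tables are TSV with a header; `#` starts a comment line; floats are
  written with 17 significant digits and re-read with round-trip parsing,
  so write-then-read is exact and a rerun with the same seed and inputs is
  byte-identical (the run manifest records config, seed and input SHA-256).
- A p-value supplied without z yields |z| via the two-sided normal
  quantile, flagged sign-unknown.
- eSNP and instrument ties break lexicographically by SNP id; CFG ties by
  total LBF then gene id.
- Genes with no scoreable eSNP, no instrument, no expression row, or too
  few case/control samples are skipped with a log message; a panel with no
  cases (or no controls) at all is an error.
- If no gene passes the corrected LBF threshold, the pipeline carries the
  top ten genes by LBF forward as candidates (logged), so all-null runs
  still exercise every stage.

## Problem sizes used in validation

The test suite and `scripts/acceptance.py` use desk-scale sizes chosen as
the package's own validation conditions: 100-instance brute-force oracle
sweeps; exact enumeration on a 6-gene background (15 possible sets)
against 10,000 permutations; 100,000 draws for the SMR null rejection
rate; 200–250 replicate all-null fixtures for the uniformity checks
(compared with the 99% Kolmogorov–Smirnov band); and 20-seed recovery
sweeps for the planted-signal analyses. The calibration fixture for the
pattern test draws 320-gene sets from a 3,320-gene background so the
integer statistic is fine-grained relative to the KS band; the power
fixtures use the 8-gene draws of the motivating study.

## Known limitations

- The LBF model is a single-parameter approximation, not the original
  hierarchical tool; printed LBF values from the real data are not
  reproducible and are not targets.
- Permutation p-values have resolution 1/n and are conservative in the
  presence of ties.
- The co-expression test correlates over samples within a cluster,
  mixing donors and regions; donor-level averaging is not offered.
- External CFG channels are taken at face value from the input table.
- Gene identifiers are opaque case-sensitive strings; no alias resolution.
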