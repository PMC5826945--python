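# sczprio

Integrative schizophrenia (SCZ) risk-gene prioritization. GWAS loci rarely
name the gene they act through; most risk variants are regulatory. This
package scores genes by combining GWAS summary statistics with brain eQTL
evidence, validates candidates with summary-data Mendelian randomization
(SMR), tests whether they are network-connected to the GWAS-significant
gene set and expressed with the early-developmental bias expected of
neurodevelopmental risk genes, tests case–control differential expression,
and accumulates everything into a convergent-functional-genomics (CFG)
ranking. It is aimed at statistical geneticists who want a transparent,
seedable, fully testable version of this evidence-integration workflow —
every stage runs on synthetic data with planted ground truth, so the
machinery is verifiable without any external downloads.

## The statistics

**Gene scoring.** For gene *g* with eSNPs *s* (eQTL p < 1e-5), each eSNP
contributes an approximate log Bayes factor from its GWAS z-score, with a
Normal(0, W) prior on the standardized effect (W = 0.15 by default):

    LBF(z; W) = ½ ln(1/(1+W)) + (z²/2) · W/(1+W),   score(g) = Σₛ LBF(zₛ)

The score is negative for eSNPs with no disease signal and positive for
associated ones; exp(score) is the odds of association versus the null
(score 5.64 ⇒ 281-fold). Significance is Monte-Carlo (matched null genes,
add-one empirical p) with Bonferroni correction — the same correction that
turns 0.05 over 8,998 genes into a per-gene threshold of 5.6e-6.

**SMR.** Per gene, the top cis-eQTL (p < 5e-8) instruments
T_SMR = z²_GWAS z²_eQTL / (z²_GWAS + z²_eQTL), referred to χ²₁.

**Network & pattern evidence.** Cross-set connectivity (edges joining
candidates to the GWAS reference set, within-set edges excluded) in a PPI
graph and in per-cluster co-expression graphs (|Pearson r| > 0.8), and the
count of candidate genes expressed higher in early development (min–max
normalized trajectories, early vs late window means). Each statistic is
compared against 1,000 size-matched random gene sets; p = k/n, reported
"< 1/n" at the resolution floor.

**CFG.** Nine one-point channels (discovery, PPI, co-expression,
differential expression, replication, SMR, plus three external-resource
channels); rank by score, ties by total LBF.

## Worked example

Simulate an input bundle with three planted risk genes, then run the full
pipeline:

```sh
sczprio simulate --seed 42 --out bundle
sczprio run-all --seed 42 \
    --gwas bundle/gwas.tsv --eqtl bundle/eqtl.tsv \
    --expr bundle/expression.tsv --meta bundle/expression_meta.tsv \
    --network bundle/network.tsv --reference bundle/reference_genes.txt \
    --clusters bundle/cluster_map.tsv --background bundle/background_genes.txt \
    --replication-eqtl bundle/replication_eqtl.tsv --truth bundle/truth.json \
    --out results
```

The run writes seven stage tables plus a manifest. The top of
`results/cfg_ranking.tsv`:

```
 rank gene_id  cfg_score  total_lbf
    1   G0068          6   8.512241
    2   G0096          6   7.402991
    3   G0075          6   6.791757
    4   G0090          0   0.649535
    5   G0005          0   0.561991
```

The three top-ranked genes are exactly the planted risk genes recorded in
`bundle/truth.json` (`G0068, G0075, G0096`): each scored six evidence
channels (significant LBF, PPI and co-expression connectivity to the
reference set, case–control shift, replication, SMR) while every null gene
scored zero. Their LBF rows show totals near 7–8.5 nats — odds of order
e⁸ ≈ 3000:1 — with empirical p at the Monte-Carlo floor (1/10,001,
Bonferroni-corrected 0.01), and the PPI permutation test reports observed
cross-connectivity 77 with p < 0.001 (no random set of matched size
reached it in 1,000 permutations). Reruns with the same seed are
byte-identical; the manifest records config, seed, and input checksums.

Every stage is also available as its own subcommand (`lbf`, `smr`,
`ppi-perm`, `coexpr-perm`, `pattern-perm`, `de`, `cfg`) on the same TSV
formats; see `sczprio --help`.

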