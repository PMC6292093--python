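# replicheck

Bayesian verification of putative sequencing replicates from
shallow-depth allelic read counts.

When an individual has been sequenced `k` times, every hypothesis about
which runs truly derive from the same genotypic source is a labeled set
partition of the `k` samples ("source vector", e.g. `1,2,1` means samples
1 and 3 share a source). `replicheck` computes the posterior probability
of every such partition directly from per-site allelic depth (AD) data —
no genotype calling, imputation or phasing — using binomial genotype
likelihoods with a symmetric sequencing error rate, Hardy–Weinberg
genotype priors built from population allele frequencies, and a uniform
prior over partitions. It is designed for low- to moderate-depth data
(GBS, skim WGS) where hard genotype calls are unreliable.

## Layout

- `replicheck.partition_model` — source-vector enumeration (restricted-
  growth strings; Bell-number counts), genotype likelihoods, HWE priors,
  per-site marginal likelihoods (block-factorized, `O(k·3)` per partition
  per site instead of `O(3^k)`), and the log-sum-exp normalized posterior.
- `replicheck.variant_io` — AD parsing from VCF (biallelic SNPs only),
  pooled-read allele-frequency estimation from a panel or a user TSV, and
  analysis-site sampling (MAF window, minimum inter-site distance,
  read-presence requirement), plus a TSV interchange format.
- `replicheck.simulator` — synthetic datasets with known truth (HWE
  genotypes, Poisson depths, error-bearing reads, optional site-level
  contamination) and drivers for the four canned experiments: a
  depth-by-MAF accuracy grid, an `L` sweep, contamination sensitivity,
  and unequal depths.
- `replicheck.cli` — the `replicheck` command.

## CLI

Score the partitions of two or more samples in a VCF (needs a per-sample
`AD` FORMAT field). Population ALT-allele frequencies come from either a
reference panel in the same file or a `chrom  pos  freq_B` TSV:

```sh
replicheck infer \
    --vcf cohort.vcf --samples runA,runB,runC \
    --panel-samples p1,p2,p3 \
    --L 1000 --maf-min 0.4 --maf-max 0.5 --min-distance 20000 \
    --error-rate 0.01 --threshold 0.99 --seed 1 \
    --out-prefix out/runABC
```

This writes `out/runABC.report.json` (full posterior, call,
non-replicate rate, echoed parameters) and a posterior TSV. Exit status
is 0 when a partition reaches the threshold and 3 on a no-call (the
distribution is still written). Joint analysis is capped at `k = 8`
samples; `k > 7` is discouraged (the partition count grows as the Bell
numbers).

Simulate a dataset or run an experiment:

```sh
replicheck simulate --true-s 1,2,1 --L 1000 --lam 3 --seed 1 --out-prefix out/sim
replicheck experiment accuracy-grid --k 3 --reps 25 --seed 1 --out-prefix out/grid
replicheck experiment sensitivity --reps 25 --seed 1 --out-prefix out/sens
```

Experiments emit a tidy per-run TSV, a per-cell summary (median/quartile
posterior of the true partition, argmax recovery rate) and a metadata
JSON with the full configuration.

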