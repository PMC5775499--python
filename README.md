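# reintropop

Population-genomic analysis of serial reintroduction bottlenecks.

A reintroduction program that founds populations step by step — a large
autochthonous source, a captive breeding stock of a few dozen founders,
primary populations bred from the captive stock, and secondary populations
founded from single primaries — leaves a genomic footprint: diversity drops
with each founding step, differentiation (FST) grows with reintroduction
rank, and long runs of homozygosity (ROH) concentrate in the most recently
founded populations. This package provides both the generative model and the
measurement toolkit for that process:

- **`reintropop.reintro_sim`** — forward Wright–Fisher simulation over a
  configurable stage graph (diploid, random mating, Haldane recombination on
  a physical marker map, no new mutation), with founder-gamete ancestry
  tracking for true identity-by-descent tracts, plus a RAD-seq-like
  observation model (negative-binomial depth, depth-threshold missingness,
  genotype error).
- **`reintropop.genotype_io`** — the shared data model (genotype matrix,
  population map, coverage profile) and VCF / population-map readers and
  writers.
- **`reintropop.panel_filters`** — SNP panel construction: genotyping-rate
  minima (presets `general`, `multispecies`, `intraspecies`), monomorphic
  and singleton/private-doubleton removal, MAF floor, coverage-based paralog
  filter, greedy distance thinning.
- **`reintropop.diversity`** — SNP density with individual-resampling
  curves, expected/observed multilocus heterozygosity and F_IS,
  Weir–Cockerham pairwise FST, genotype-covariance PCA.
- **`reintropop.roh`** — plink-style windowed ROH calling (25-SNP windows,
  5% hit threshold, 1 Mb / 25 SNP / 1-het segment rules, 50 kb/SNP density,
  1 Mb gap split), length-class summaries, and the F_ROH inbreeding
  coefficient (ROH > 10 Mb over autosome length).
- **`reintropop.ne_est`** — three effective-population-size estimators:
  LD-based (Burrows composite r² with sample-size correction and an
  individual-block jackknife CI), heterozygosity-loss inversion
  (`H_{t+1} = (1 − 1/2Ne) H_t`), and the Wright drift-FST inversion
  (`1 − FST = (1 − 1/2Ne)^t`) with its forward companion.
- **`reintropop.cli_pipeline`** — a `reintropop` CLI and a seeded,
  deterministic pipeline producing VCF, population map, diversity /
  resampling / FST / ROH / Ne report tables and a run manifest.

## CLI

```sh
# simulate a reintroduction and run the full analysis
reintropop simulate --config run.yaml --seed 1 --out out/

# analyze an existing VCF + population map (individual<TAB>population<TAB>role)
reintropop analyze --vcf data.vcf --popmap popmap.tsv --out out/

# single stages
reintropop diversity --vcf out/simulated.vcf --popmap out/popmap.tsv
reintropop roh --vcf out/simulated.vcf --out roh.bed
reintropop ne --vcf out/simulated.vcf --popmap out/popmap.tsv
```

The YAML config accepts `demography`, `genome`, `observation`, `panel`,
`roh`, `ne`, and `resampling` blocks (see `RunConfig` in
`reintropop/cli_pipeline.py`); unknown keys are rejected with their path.
Identical config + seed reproduces byte-identical report files.

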