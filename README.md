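# diffmnase

Differential MNase-seq simulation and analysis toolkit.

Chromatin digested with low (partial) vs high (complete) concentrations of
micrococcal nuclease releases nucleosomal DNA differentially. This package
implements both sides of that strategy:

* **`array_simulator`** — a stochastic model of MNase digestion of a regular
  50-nucleosome array (one candidate cleavage site per linker and per
  nucleosome, weighted sampling without replacement of cut events, exact
  mono-nucleosomal fragment selection and end trimming), including scenario
  weight maps for compacted domains, AT-sensitive nucleosomes and fragile
  hyper-accessible sites.
* **`synthetic_data`** — genome-scale synthetic inputs (FASTA, per-condition
  fragment BEDs, mappability, CNV segments, ground-truth bundle) with
  GC-varying domains, optional 10-bp dinucleotide phasing at dyads, a
  condition-asymmetric AT sensitivity that reproduces the GC bias of
  complete digestion, and planted hyper-accessible sites.
* **`fragment_processing`** — fragment parsing (BED/BEDPE), mono/di size
  selection (140–200 / 250–500 bp inclusive), Poisson-tail clonal filtering,
  midpoint-extended occupancy tracks (70 bp mono / 150 bp di), depth
  normalization, CNV correction and a simple nucleosome position caller.
* **`domain_analysis`** — constant-size window statistics (occupancy means,
  GC, mappability with the 0.9 exclusion), log2 fold changes, and OLS
  regression on GC with one pass of Cook's-distance influence filtering.
* **`gc_normalization`** — LOESS (tricube local polynomial) fit of occupancy
  vs GC in 250-bp windows (30–70 % GC gate) and multiplicative correction.
* **`differential_sites`** — per-base Poisson-rate comparison of corrected
  tracks, merging into candidate intervals (min width 70 bp, base p < 1e-2),
  interval-level testing with genome-wide Benjamini–Hochberg control
  (FDR < 0.05), plus Fisher-exact overlap enrichment of site sets.
* **`profiles`** — fragment GC content, dinucleotide-set frequency around
  fragment midpoints/borders (±300 bp at 1-bp resolution), a spectral score
  for the ~10-bp nucleosomal periodicity, random fragment controls, and
  feature-anchored aggregate profiles/heatmaps.
* **`pipeline` / `cli`** — end-to-end orchestration with a recovery report
  against the planted truth.

## CLI

```sh
# digest a nucleosome array under both conditions
diffmnase simulate-array --scenario fragile_site --fragments 1000000 \
    --seed 1 --out arr

# build a synthetic dataset (genome FASTA, fragment BEDs, truth bundle)
diffmnase synth-genome --genome-kind biased --chrom-len 2000000 \
    --n-fragments 500000 --seed 1 --out data/

# occupancy track from fragments
diffmnase occupancy --fragments data/fragments_low.bed \
    --chrom-sizes data/genome.chrom.sizes --target 2e8 --out low.bedGraph

# windowed statistics + GC regression
diffmnase windows --low low.bedGraph --high high.bedGraph \
    --genome data/genome.fa --window 1000000 --out win

# LOESS GC normalization and differential site calling
diffmnase gcnorm --low low.bedGraph --high high.bedGraph \
    --genome data/genome.fa --out norm
diffmnase diffsites --low norm.low.gcnorm.bedGraph \
    --high norm.high.gcnorm.bedGraph \
    --chrom-sizes data/genome.chrom.sizes --out sites.bed

# everything at once, from a YAML config
diffmnase full-pipeline --config config.yaml --out run/
```

A minimal `config.yaml`:

```yaml
genome: biased        # or "null" for the no-difference control genome
seed: 1
chrom_len: 5000000
n_hyper_sites: 50
n_fragments: 2000000
window_sizes: [5000, 100000, 1000000]
fdr: 0.05
```

## Conventions

All coordinates are 0-based half-open (BED standard); fragment midpoints use
the floor convention. Occupancy tracks carry an explicit normalization log so
incompatible tracks cannot be compared accidentally. All stochastic steps
take explicit seeds and are reproducible bit-for-bit.
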