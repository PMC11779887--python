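# atacbench

Comparison machinery for **bulk vs single-cell ATAC-seq**: how much of the
regulatory landscape does each technology see, how many cells does a
pseudo-bulk track need, and how few cells can still form their own cluster?

Chromatin accessibility assays tagment open chromatin with Tn5 and sequence
the resulting fragments. Aggregating ("pseudo-bulking") barcoded single-cell
fragments produces a track directly comparable to bulk ATAC-seq, but the two
technologies differ in background composition and in per-site sensitivity —
most visibly for weak open-chromatin classes such as CTCF-bound boundary
elements and primed enhancers. `atacbench` implements the full analysis
stack needed to quantify those differences, exercised end-to-end on
synthetic fragment data with known ground truth:

- **Synthetic data** (`atacbench.synth`) — genomes, regulatory elements of
  graded accessibility (promoter 0.9 > enhancer 0.5 > primed enhancer 0.25 >
  CTCF 0.12), ChIP-mark tracks (H3K4me1/H3K4me3/H3K27ac/CTCF + input), and
  barcoded fragments whose lengths follow a three-component log-normal
  mixture with sub- (~80 bp), mono- (~185 bp) and di-nucleosomal (~370 bp)
  modes and depletions near 150/300 bp.
- **Signal** (`atacbench.signal`) — pseudo-bulk coverage (raw or RPKM =
  raw · 10⁹ / (total fragments · bin size)), coverage-level histograms,
  off-peak region sampling and pile-ups, stratified fragment-size
  distributions.
- **Peaks** (`atacbench.peaks`) — a sliding-window Poisson-enrichment caller
  scoring peaks in [0, 1] (retention: score > 0.5, blacklist removal),
  bedtools-style left-outer-join intersection, union-peak Venn partition,
  and strand-aware genomic-location annotation.
- **Classification** (`atacbench.classify`) — peak windows extended ±2 kb
  from their centers, mean mark coverage per window, rule-based labels
  (Promoter / Enhancer / CTCF / Promoter/CTCF / Enhancer/CTCF /
  Unclassified), "classical CTCF" site extraction, and the detection
  sensitivity statistic: of *n* reference sites, the count and percentage
  overlapping a called peak set.
- **Resampling** (`atacbench.resampling`) — cell-level barcode downsampling,
  Bernoulli fragment thinning for depth-matched comparisons, sensitivity
  curves, and spike-in dilution of one population into a heterogeneous
  background.
- **Clustering** (`atacbench.clustering`) — binary cells × 500 bp tile
  matrix, TF-IDF/LSI embedding (truncated SVD, depth-tracking first
  component dropped), kNN + Leiden communities, and spike-in recovery
  metrics (modal-cluster recall and purity).
- **Pipeline** (`atacbench.pipeline`, CLI `atacbench`) — the three
  experiments (`compare`, `downsample`, `dilute`) from one flat YAML config,
  with manifests and seeded, reproducible randomness.

## Worked example

`examples/04_downsampling_curve.py` simulates a 1,000-cell library over a
known element truth, then re-calls peaks on random barcode subsets:

```
cells            promoter          enhancer   primed_enhancer              ctcf
 1000              100.0%            100.0%            100.0%             83.5%
  500              100.0%            100.0%            100.0%             31.5%
  200              100.0%            100.0%             78.0%              1.0%
  100              100.0%             98.0%             29.5%              1.0%
   50               97.0%             47.5%              4.5%              0.0%
```

Each entry is the percentage of true elements of that class overlapped by a
called peak (score > 0.5). Strong promoters survive to 50 cells almost
intact, while weak CTCF sites are the first casualties of reduced cell
number — the central sensitivity asymmetry this package quantifies.
`examples/05_spikein_clustering.py` shows the complementary clustering
result: 80 spiked cells form their own pure cluster (recall 1.00, purity
1.00) in a 2,350-cell background, while 20 cells are absorbed into an
existing cluster. The other examples cover simulation, peak calling with
Venn partition, and ChIP-mark classification.

A shell entry point mirrors the library:

```bash
atacbench simulate --seed 1 --out sim/
atacbench peaks call sim/fragments.tsv --chrom-sizes sim/chrom.sizes --out peaks.bed
atacbench run --experiment downsample --seed 1 --out reports/
```

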