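# Methods

## What the generator emulates

The synthetic-data module produces barcoded tagmentation fragments with the
statistical structure that drives bulk vs single-cell ATAC comparisons.

**Fragment lengths.** Tn5 cuts preferentially in linker DNA, so fragment
lengths form a mixture of sub-nucleosomal, mono-nucleosomal and
di-nucleosomal classes. We model lengths as a three-component log-normal
mixture with modes 80 / 185 / 370 bp and log-scale sigmas 0.38 / 0.14 /
0.10, chosen so the mixture density has local minima in the
nucleosome-protected troughs (~138 bp and ~287 bp with the default weights).
Default weights encode the technology contrast:

| stratum | sub | mono | di |
|---|---|---|---|
| single-cell, in peak | 0.55 | 0.35 | 0.10 |
| single-cell, off peak | 0.30 | 0.55 | 0.15 |
| bulk, in peak | 0.50 | 0.40 | 0.10 |
| bulk, off peak | 0.60 | 0.30 | 0.10 |

i.e. single-cell signal is enriched for short nucleosome-free fragments,
single-cell background shifts toward mono-nucleosomal fragments, and bulk
background is sub-nucleosomal-rich. Lengths are clipped to [20, 1000] bp.

**Elements.** Four classes with graded per-cell capture weight — promoter
0.9, enhancer 0.5, primed enhancer 0.25, CTCF 0.12 — so that the weakest
classes are lost first as depth falls. Elements are non-overlapping,
default width 400 bp, separated by ≥ 3.6 kb. The wide gap keeps a ±2 kb
classification window around one element from touching its neighbours,
mirroring the sparsity of regulatory elements in a mammalian genome; the
default genome (2 × 2.5 Mb, 800 elements) has roughly the same
elements-per-Mb density ratio to window size as real data.

**Fragment generation.** Each cell draws a fragment count from a negative
binomial (default mean 400, shape 10). A fragment is in-peak with
probability `in_peak_fraction` (0.55 single-cell, 0.35 bulk); in-peak
fragments pick an element accessible in the cell's population with
probability proportional to element strength and are centred uniformly
within it; off-peak fragments land uniformly on the genome. Bulk libraries
collapse onto a single pseudo-barcode. The duplicate-count column is always
1 (PCR duplication out of scope). Population structure: a configurable
fraction of elements is shared housekeeping (accessible everywhere); the
rest are private to one population, assigned round-robin or by explicit
weights (used to make the spike-in population's repertoire distinct).

**ChIP tracks.** Each mark deposits ~Poisson(60) fragments of 200 bp per
bound element (H3K4me3 on promoters; H3K4me1 on enhancers and primed
enhancers; H3K27ac on promoters and active enhancers; CTCF on CTCF elements
plus a co-binding fraction, default 0.25, of promoters/enhancers — the
source of the combined Promoter/CTCF and Enhancer/CTCF classes), over
uniform Poisson background (default 0.002 fragments/bp). An input track
containing only the background process is emitted as the classification
reference.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: sequence content and Tn5 insertion bias, PCR
duplicates and doublets, mitochondrial contamination, copy-number and
mappability artifacts, non-uniform (clumpy) background, and correlated
element co-accessibility beyond the population masks. Conclusions here are
about the pipeline's statistical machinery, not about any particular
biological dataset.

## Scale of the default study conditions

The default simulation uses a 5 Mb genome, 200 elements per class, 2,000
single cells at 400 fragments/cell, chosen so the full three-experiment
suite runs in minutes on one CPU while preserving the regimes that matter:
peak calling is background-limited for weak elements at low cell counts and
saturated for promoters, and the per-cell tile matrix has realistic
sparsity (~1–2% of usable tiles per cell). Bulk libraries default to ~11%
of the single-cell fragment total, the depth ratio of typical matched
designs, which is what makes bulk blind to weak CTCF sites in the
`compare` experiment. Real datasets are three orders of magnitude larger in
both genome and reads; absolute percentages from the simulation are not
comparable to published values, but orderings and trends are.

## Peak caller

The caller is a deterministic sliding-window Poisson-enrichment scorer that
deliberately exposes the same contract as the neural-network callers used
on real data (per-peak score in [0, 1]; retain score > 0.5): it is the
interface, not the CNN, that the downstream machinery depends on.

Per-base coverage is heavily autocorrelated along each fragment's
footprint, so window sums of coverage are first converted to **effective
fragment counts** (window sum ÷ mean fragment length, default 185 bp),
which are approximately Poisson. A window (default 300 bp) is a candidate
when its effective count exceeds the Poisson upper-tail quantile (default
tail 10⁻⁶) at rate max(global mean, local background over a 10 kb span).
Overlapping candidate windows merge into peaks (minimum width 150 bp); each
peak is scored s = 1 − P(Pois(λ_local) ≥ observed) with the local rate
estimated from the 10 kb flanks excluding the peak itself, floored by the
global mean. On noise-only tracks the caller averages ≤ 1 false peak per
Mb. Known limitation: with a uniform simulated background the caller is
better calibrated than any caller is on real, clumpy background.

## Classification

Peaks are extended 2 kb from their centers; the mean per-bp coverage of
each mark over the window is compared against an enrichment threshold of
2× the reference level (configurable). The reference is the genome-wide
mean of the input track when present, else the genome-wide mean of the mark
itself — on a small dense synthetic genome the mark's own mean is inflated
by signal, so the pipeline always supplies the input track. Label rules:
H3K4me3 ⇒ Promoter; else H3K4me1 ⇒ Enhancer; CTCF combines or stands
alone; nothing ⇒ Unclassified.

`detection_sensitivity` truncates its percentage to two decimals; this
matches the arithmetic of the published counts it is tested against
(17,387/22,072 → 78.77; 1,054/22,072 → 4.77; 5,029/22,072 → 22.78 — the
middle value would print 4.78 under half-up rounding).

## Resampling and clustering

Downsampling is strictly cell-level: a uniform random barcode subset, each
kept cell's fragments carried over exactly. Depth matching between
technologies uses per-fragment Bernoulli thinning instead. Dilution merges
n randomly chosen spike cells (barcodes suffix-disambiguated with
`::spike`) into a 7-population background with sizes 842 / 758 / 288 / 198
/ 129 / 106 / 29 — a PBMC-like composition spanning two orders of
magnitude.

Clustering is single-pass LSI: tiles ranked by cell frequency (top 20,000
kept), TF = row-normalised counts, IDF = log(1 + n_cells/tile frequency),
transform log(1 + TF·IDF·10⁴), seeded truncated SVD (30 components), first
component dropped as depth-correlated. Iterative LSI adds robustness on
real data but is unnecessary at simulation scale. Communities come from a
kNN graph (k = 20, Euclidean) under Leiden with resolution 1.0; k and
resolution are this package's defaults, exposed in the config. Spike-in
recovery is scored by the spike population's modal cluster: success iff
recall ≥ 0.8 and purity ≥ 0.5. The thresholds operationalise a judgement
published work makes visually from embeddings; both are configurable. The
tile-matrix cell filter defaults to 100 fragments/cell, scaled to the
simulator's default per-cell depth (real-data pipelines use 1,000 at ~25×
higher per-cell depth).

## Numerical and design choices

- Coordinates are 0-based half-open everywhere; chromosome order comes from
  the genome model, never lexicographic sorting.
- Fragment-level counting throughout; where read counts are discussed the
  conversion is 2 reads per fragment.
- In-peak assignment uses a ≥ 1 bp overlap rule.
- Off-peak region sampling draws distinct start positions uniformly from
  the exclusion complement (regions may overlap each other) by rejection
  with a deterministic cap of 1000 × n attempts.
- Venn partition counts maximal merged union peaks (bookended intervals
  merge); a union peak is common iff covered by at least one peak from each
  input.
- Location annotation is summit-based with precedence promoter ≤ 1 kb >
  promoter 1–3 kb > exonic > intronic > distal; TSS distance is
  strand-aware (gene start on +, gene end on −).
- Ties in the K4me1 − K4me3 ordering break by genomic coordinate (stable).
- All randomness flows from explicit integer seeds; multi-stage experiments
  split one root seed via numpy `SeedSequence` with derived seeds kept
  below 2³¹. Fixed seeds give byte-identical outputs.
- Degenerate inputs: empty barcode selections yield empty tracks (not
  errors); unknown barcodes warn and are ignored; rank-deficient tile
  matrices warn and return fewer LSI components; empty reference sets for
  the sensitivity statistic are an error (the percentage is undefined).
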