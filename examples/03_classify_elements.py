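"""Classify open-chromatin peaks by ChIP-mark signatures.

Simulates H3K4me1 / H3K4me3 / H3K27ac / CTCF coverage consistent with the
element truth, extends each element 2 kb from its center, and labels every
window (Promoter, Enhancer, CTCF, combined, or Unclassified). Also computes
the classical-CTCF detection statistic: the fraction of CTCF sites devoid of
enhancer/promoter marks that overlap a called peak set.
"""

from collections import Counter

from atacbench import (
    aggregate_coverage,
    build_genome,
    call_peaks,
    classical_ctcf_set,
    classify_elements,
    detection_sensitivity,
    extend_from_center,
    filter_peaks,
    mark_coverage_matrix,
    place_elements,
    simulate_chip_tracks,
    simulate_fragments,
    single_cell_profile,
)

genome = build_genome(2, 1_000_000, seed=7)
elements = place_elements(
    genome, {"promoter": 30, "enhancer": 30, "primed_enhancer": 30, "ctcf": 30}, seed=7
)
chip, chip_truth = simulate_chip_tracks(elements, genome, seed=8)

windows = extend_from_center([e.interval for e in elements], flank=2000)
labels = classify_elements(mark_coverage_matrix(windows, chip), chip)
print("window labels:", dict(Counter(labels)))

# classical CTCF sites = CTCF ChIP peaks with no K4me1/K4me3 overlap
classical = classical_ctcf_set(
    chip_truth["CTCF"], chip_truth["H3K4me1"], chip_truth["H3K4me3"]
)
frags, _ = simulate_fragments(elements, genome, single_cell_profile(500, 400.0), seed=9)
called = filter_peaks(call_peaks(aggregate_coverage(frags, genome=genome)), 0.5)
n_ref, n_det, pct = detection_sensitivity(classical, called)
print(f"classical CTCF sites: {n_ref}; detected by ATAC peaks: {n_det} ({pct}%)")
print("(these weak boundary elements are the hardest class to detect)")
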