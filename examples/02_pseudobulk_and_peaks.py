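"""Pseudo-bulk two technologies, call peaks, and Venn-partition the peak sets.

Simulates matched single-cell and bulk libraries from one element truth
(bulk at ~11% of the single-cell depth, mirroring typical sequencing
budgets), aggregates each into a coverage track, calls Poisson-enrichment
peaks, retains score > 0.5, and partitions the union. Single-cell should
recover nearly every bulk peak plus many extra weak sites.
"""

from atacbench import (
    aggregate_coverage,
    build_genome,
    bulk_profile,
    call_peaks,
    filter_peaks,
    place_elements,
    simulate_fragments,
    single_cell_profile,
    venn_partition,
)

genome = build_genome(2, 1_000_000, seed=3)
elements = place_elements(
    genome, {"promoter": 40, "enhancer": 40, "primed_enhancer": 40, "ctcf": 40}, seed=3
)

sc_frags, _ = simulate_fragments(
    elements, genome, single_cell_profile(800, 400.0), seed=4
)
bulk_frags, _ = simulate_fragments(
    elements, genome, bulk_profile(800, 44.0), seed=5
)

sc_peaks = filter_peaks(call_peaks(aggregate_coverage(sc_frags, genome=genome)), 0.5)
bulk_peaks = filter_peaks(call_peaks(aggregate_coverage(bulk_frags, genome=genome)), 0.5)
venn = venn_partition(bulk_peaks, sc_peaks)

print(f"single-cell peaks: {len(sc_peaks)}, bulk peaks: {len(bulk_peaks)}")
print(
    f"venn: bulk-only={venn.n_only_a}  sc-only={venn.n_only_b}  "
    f"common={venn.n_common}  total={venn.total}"
)
print("(almost every bulk peak is inside the single-cell set;")
print(" the sc-only peaks are the weak elements bulk depth cannot resolve)")
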