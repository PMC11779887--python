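import numpy as np
import pytest

from atacbench import (
    FragmentSet,
    build_genome,
    place_elements,
    simulate_fragments,
    single_cell_profile,
)


@pytest.fixture(scope="session")
def genome_small():
    return build_genome(2, 100_000, seed=7)


@pytest.fixture(scope="session")
def elements_small(genome_small):
    return place_elements(
        genome_small,
        {"promoter": 5, "enhancer": 5, "primed_enhancer": 5, "ctcf": 5},
        element_width=200,
        min_gap=500,
        seed=3,
    )


@pytest.fixture(scope="session")
def frags_small(genome_small, elements_small):
    """~50 cells x 200 fragments on the small genome."""
    profile = single_cell_profile(n_cells=50, mean_fragments=200.0)
    frags, truth = simulate_fragments(elements_small, genome_small, profile, seed=11)
    return frags, truth


def random_intervals(rng, n, chroms=("chr1", "chr2"), max_pos=10_000, max_width=400):
    """Random interval tuples for oracle comparisons."""
    from atacbench import Interval

    out = []
    for _ in range(n):
        chrom = chroms[rng.integers(0, len(chroms))]
        start = int(rng.integers(0, max_pos))
        width = int(rng.integers(1, max_width))
        out.append(Interval(chrom, start, start + width))
    return out


def brute_force_overlaps(a, b):
    """All-pairs overlap enumeration (the quadratic oracle)."""
    pairs = []
    for iv in a:
        hits = [jv for jv in b if iv.overlaps(jv)]
        pairs.append((iv, hits))
    return pairs
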