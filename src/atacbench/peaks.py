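"""Peak calling, filtering, interval algebra and location annotation.

The caller is a sliding-window Poisson-enrichment scorer exposing the same
contract as neural-network callers used in practice: every peak carries a
score in [0, 1] and the downstream retention convention is strictly greater
than 0.5. Window sums of base-pair coverage are converted into effective
fragment counts (window sum / mean fragment length) so that the Poisson model
applies to approximately independent events rather than to per-base coverage,
which is heavily autocorrelated along a fragment's footprint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence, Union

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import poisson

from .core import CoverageTrack, Interval, Peak

LOCATION_CATEGORIES = (
    "promoter_le1kb",
    "promoter_1to3kb",
    "exonic",
    "intronic",
    "distal_intergenic",
)


@dataclass(frozen=True)
class Gene:
    """A stranded gene body with exons; the TSS is strand-aware."""

    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]
    name: Optional[str] = None

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end


@dataclass
class GeneModel:
    genes: list[Gene]


class OverlapRecord(NamedTuple):
    """One row of a left-outer-join overlap table (bedtools -loj semantics)."""

    a: Union[Interval, Peak]
    b: Optional[Union[Interval, Peak]]


@dataclass
class VennResult:
    """Union-peak partition of two peak sets.

    The merged union of both sets is split into maximal non-overlapping
    union peaks; each is ``common`` iff covered by at least one peak from
    each input set, else ``only_a`` / ``only_b``. Counts are additive over
    the union by construction.
    """

    only_a: list[Interval]
    only_b: list[Interval]
    common: list[Interval]

    @property
    def n_only_a(self) -> int:
        return len(self.only_a)

    @property
    def n_only_b(self) -> int:
        return len(self.only_b)

    @property
    def n_common(self) -> int:
        return len(self.common)

    @property
    def total(self) -> int:
        return self.n_only_a + self.n_only_b + self.n_common


@dataclass
class LocationAnnotation:
    categories: list[str]  # per peak, aligned to input order
    counts: dict[str, int]


@dataclass(frozen=True)
class CallerParams:
    """Tunables of the Poisson sliding-window caller."""

    window: int = 300  # bp, candidate window width
    local_bg_span: int = 10_000  # bp, span for the local background rate
    min_width: int = 150  # bp, minimal peak width retained
    tail: float = 1e-6  # Poisson upper-tail probability for candidacy
    mean_fragment_length: float = 185.0  # bp, converts coverage to counts


# ------------------------------------------------------------------ calling


def _moving_sum(x: np.ndarray, w: int) -> np.ndarray:
    """Sums of x over sliding windows of width w (length len(x) - w + 1)."""
    c = np.concatenate(([0.0], np.cumsum(x)))
    return c[w:] - c[:-w]


def _centered_mean(x: np.ndarray, span: int) -> np.ndarray:
    """Mean of x over a centered window of ~span elements, edge-truncated."""
    n = len(x)
    c = np.concatenate(([0.0], np.cumsum(x)))
    half = span // 2
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    return (c[hi] - c[lo]) / (hi - lo)


def _poisson_isf_quantized(tail: float, lam: np.ndarray) -> np.ndarray:
    """poisson.isf over an array, computed once per quantized rate."""
    lam_q = np.round(np.maximum(lam, 1e-9), 3)
    uniq, inverse = np.unique(lam_q, return_inverse=True)
    return poisson.isf(tail, uniq)[inverse]


def call_peaks(
    track: CoverageTrack, params: CallerParams = CallerParams()
) -> list[Peak]:
    """Call enrichment peaks on a raw coverage track.

    Candidate windows whose effective fragment count exceeds the Poisson
    upper tail of max(global mean, local background) are merged into peaks.
    Each peak is scored s = 1 - P(Pois(lambda_local) >= observed), clamped to
    [0, 1]; the summit is the offset of maximal signal. Deterministic.
    """
    if track.normalization != "raw":
        raise ValueError("call_peaks requires a raw track")
    b = track.bin_size
    w_bins = max(1, params.window // b)
    span_bins = max(w_bins, params.local_bg_span // b)
    flen = params.mean_fragment_length

    out: list[Peak] = []
    for chrom in track.genome.chrom_names:
        x = track.data[chrom]
        if len(x) < w_bins or x.sum() == 0:
            continue
        global_rate = float(x.mean())  # coverage per bin
        local_rate = _centered_mean(x, span_bins)

        window_sums = _moving_sum(x, w_bins)  # per candidate start
        centers = np.arange(len(window_sums)) + w_bins // 2
        bg_rate = np.maximum(local_rate[centers], global_rate)
        lam_eff = bg_rate * w_bins * b / flen
        n_eff = window_sums * b / flen
        cand = n_eff > _poisson_isf_quantized(params.tail, lam_eff)
        if not cand.any():
            continue

        # merge overlapping candidate windows [i, i + w_bins)
        idx = np.flatnonzero(cand)
        breaks = np.flatnonzero(np.diff(idx) > w_bins)
        run_starts = np.concatenate(([0], breaks + 1))
        run_ends = np.concatenate((breaks, [len(idx) - 1]))
        for rs, re in zip(run_starts, run_ends):
            s_bin, e_bin = int(idx[rs]), int(idx[re]) + w_bins
            start, end = s_bin * b, min(e_bin * b, track.genome.length_of(chrom))
            if end - start < params.min_width:
                continue
            seg = x[s_bin:e_bin]
            obs_eff = float(seg.sum()) * b / flen
            # local background around (not under) the peak, floored globally
            flank = span_bins
            lo, hi = max(0, s_bin - flank), min(len(x), e_bin + flank)
            n_out = (hi - lo) - (e_bin - s_bin)
            bg = (float(x[lo:hi].sum()) - float(seg.sum())) / n_out if n_out > 0 else 0.0
            rate = max(bg, global_rate)
            lam = rate * (e_bin - s_bin) * b / flen
            p_tail = float(poisson.sf(max(obs_eff - 1.0, 0.0), lam))
            score = float(np.clip(1.0 - p_tail, 0.0, 1.0))
            summit = int(np.argmax(seg)) * b + b // 2
            summit = min(summit, end - start - 1)
            out.append(Peak(chrom, start, end, score=score, summit=summit))
    return out


def filter_peaks(
    peaks: Sequence[Peak],
    min_score: float = 0.5,
    blacklist: Optional[Sequence[Union[Interval, Peak]]] = None,
) -> list[Peak]:
    """Keep peaks with score strictly > min_score and no blacklist overlap."""
    trees = _build_trees(blacklist or [])
    kept = []
    for p in peaks:
        if p.score <= min_score:
            continue
        tree = trees.get(p.chrom)
        if tree is not None and tree.overlaps(p.start, p.end):
            continue
        kept.append(p)
    return kept


# ----------------------------------------------------------- interval algebra


def _build_trees(
    intervals: Sequence[Union[Interval, Peak]]
) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
    return trees


def intersect_loj(
    a: Sequence[Union[Interval, Peak]], b: Sequence[Union[Interval, Peak]]
) -> list[OverlapRecord]:
    """Left outer join on overlap: one record per (a, overlapping b) pair;
    a-intervals without any overlap appear once with partner None."""
    trees = _build_trees(b)
    records: list[OverlapRecord] = []
    for iv in a:
        tree = trees.get(iv.chrom)
        hits = sorted(tree.overlap(iv.start, iv.end), key=lambda h: (h.begin, h.end)) if tree else []
        if hits:
            records.extend(OverlapRecord(iv, h.data) for h in hits)
        else:
            records.append(OverlapRecord(iv, None))
    return records


def merge_union(
    a: Sequence[Union[Interval, Peak]], b: Sequence[Union[Interval, Peak]]
) -> list[Interval]:
    """Maximal non-overlapping union intervals of a ∪ b (bookended intervals
    are merged)."""
    ivs = [(iv.chrom, iv.start, iv.end) for iv in list(a) + list(b)]
    ivs.sort()
    merged: list[Interval] = []
    for chrom, start, end in ivs:
        if merged and merged[-1].chrom == chrom and start <= merged[-1].end:
            last = merged.pop()
            merged.append(Interval(chrom, last.start, max(last.end, end)))
        else:
            merged.append(Interval(chrom, start, end))
    return merged


def venn_partition(
    a: Sequence[Union[Interval, Peak]], b: Sequence[Union[Interval, Peak]]
) -> VennResult:
    """Partition the merged union of two peak sets into only_a / only_b / common."""
    union = merge_union(a, b)
    trees_a, trees_b = _build_trees(a), _build_trees(b)
    only_a, only_b, common = [], [], []
    for iv in union:
        in_a = iv.chrom in trees_a and trees_a[iv.chrom].overlaps(iv.start, iv.end)
        in_b = iv.chrom in trees_b and trees_b[iv.chrom].overlaps(iv.start, iv.end)
        if in_a and in_b:
            common.append(iv)
        elif in_a:
            only_a.append(iv)
        else:
            only_b.append(iv)
    return VennResult(only_a=only_a, only_b=only_b, common=common)


# --------------------------------------------------------------- annotation


def annotate_location(
    peaks: Sequence[Peak], genes: GeneModel
) -> LocationAnnotation:
    """Annotate each peak by its summit position relative to the gene model.

    Precedence: promoter_le1kb > promoter_1to3kb > exonic > intronic >
    distal_intergenic. TSS distance is strand-aware (TSS = gene start on +,
    gene end on -).
    """
    tss_by_chrom: dict[str, np.ndarray] = {}
    exon_trees: dict[str, IntervalTree] = {}
    gene_trees: dict[str, IntervalTree] = {}
    for g in genes.genes:
        tss_by_chrom.setdefault(g.chrom, [])
        tss_by_chrom[g.chrom].append(g.tss)
        gene_trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g)
        for es, ee in g.exons:
            if es < ee:
                exon_trees.setdefault(g.chrom, IntervalTree()).addi(es, ee, g)
    tss_sorted = {c: np.sort(np.asarray(v)) for c, v in tss_by_chrom.items()}

    categories = []
    for p in peaks:
        pos = p.summit_position
        tss = tss_sorted.get(p.chrom)
        dist = None
        if tss is not None and len(tss):
            j = int(np.searchsorted(tss, pos))
            cands = [tss[k] for k in (j - 1, j) if 0 <= k < len(tss)]
            dist = min(abs(pos - t) for t in cands)
        if dist is not None and dist <= 1000:
            categories.append("promoter_le1kb")
        elif dist is not None and dist <= 3000:
            categories.append("promoter_1to3kb")
        elif p.chrom in exon_trees and exon_trees[p.chrom].overlaps(pos, pos + 1):
            categories.append("exonic")
        elif p.chrom in gene_trees and gene_trees[p.chrom].overlaps(pos, pos + 1):
            categories.append("intronic")
        else:
            categories.append("distal_intergenic")

    counts = {c: 0 for c in LOCATION_CATEGORIES}
    for c in categories:
        counts[c] += 1
    return LocationAnnotation(categories=categories, counts=counts)


def peaks_to_bed(peaks: Sequence[Peak]) -> pd.DataFrame:
    """BED6+ frame: BED score column = round(1000 x score), plus true score
    and summit as extra columns."""
    return pd.DataFrame(
        {
            "chrom": [p.chrom for p in peaks],
            "start": [p.start for p in peaks],
            "end": [p.end for p in peaks],
            "name": [p.name or f"peak_{i}" for i, p in enumerate(peaks)],
            "score": [round(1000 * p.score) for p in peaks],
            "strand": ["." for _ in peaks],
            "true_score": [p.score for p in peaks],
            "summit": [p.summit for p in peaks],
        }
    )
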