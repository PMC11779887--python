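"""Tile-matrix construction, TF-IDF/LSI embedding, graph clustering and
spike-in cluster-recovery metrics.

A single-pass latent semantic indexing (TF-IDF + truncated SVD) on a binary
cells x 500 bp tiles matrix, followed by a kNN graph and Leiden community
detection — the standard scATAC embedding/clustering stack at simulation
scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import TruncatedSVD
from sklearn.neighbors import NearestNeighbors

from .core import FragmentSet, GenomeModel


@dataclass
class CellByTileMatrix:
    """Sparse binary cells x fixed-width tiles accessibility matrix."""

    matrix: sp.csr_matrix  # binary
    barcodes: list[str]
    tile_names: list[str]
    tile_size: int

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.barcodes), len(self.tile_names)):
            raise ValueError("matrix shape does not match names")

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_tiles(self) -> int:
        return self.matrix.shape[1]


@dataclass
class Embedding:
    """LSI cell embedding; rows aligned to ``barcodes``."""

    coordinates: np.ndarray
    barcodes: list[str]
    dropped_first: bool

    def __post_init__(self) -> None:
        if not np.isfinite(self.coordinates).all():
            raise ValueError("non-finite embedding coordinates")
        if self.coordinates.shape[0] != len(self.barcodes):
            raise ValueError("rows not aligned to barcodes")


@dataclass
class SpikeInEntry:
    """Cluster-recovery metrics for one dilution level."""

    n_spike: int
    n_clusters: int
    majority_cluster_recall: float
    majority_cluster_purity: float
    success: bool


@dataclass
class SpikeInReport:
    entries: list[SpikeInEntry]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_spike": [e.n_spike for e in self.entries],
                "n_clusters": [e.n_clusters for e in self.entries],
                "recall": [e.majority_cluster_recall for e in self.entries],
                "purity": [e.majority_cluster_purity for e in self.entries],
                "success": [e.success for e in self.entries],
            }
        )


def build_tile_matrix(
    frags: FragmentSet,
    genome: Optional[GenomeModel] = None,
    tile_size: int = 500,
    min_frags_per_cell: int = 100,
) -> CellByTileMatrix:
    """Binarized midpoint-in-tile matrix; cells below the fragment filter are
    dropped."""
    if tile_size < 100:
        raise ValueError("tile_size must be >= 100")
    genome = genome or frags.genome
    if genome is None:
        raise ValueError("a genome model is required")

    df = frags.frame
    per_cell = df.groupby("barcode")["count"].sum()
    keep = per_cell[per_cell >= min_frags_per_cell].index
    if not len(keep):
        raise ValueError("no cells pass the fragment filter")
    df = df[df["barcode"].isin(set(keep))]

    barcodes = sorted(df["barcode"].unique().tolist())
    bc_index = {b: i for i, b in enumerate(barcodes)}

    tile_offsets = {}
    tile_names: list[str] = []
    offset = 0
    for chrom in genome.chrom_names:
        n_tiles = -(-genome.length_of(chrom) // tile_size)
        tile_offsets[chrom] = offset
        tile_names.extend(
            f"{chrom}:{i * tile_size}-{(i + 1) * tile_size}" for i in range(n_tiles)
        )
        offset += n_tiles

    rows = df["barcode"].map(bc_index).to_numpy()
    mids = ((df["start"].to_numpy() + df["end"].to_numpy()) // 2) // tile_size
    cols = df["chrom"].map(tile_offsets).to_numpy() + mids
    data = np.ones(len(df), dtype=np.int8)
    mat = sp.coo_matrix(
        (data, (rows, cols)), shape=(len(barcodes), len(tile_names))
    ).tocsr()
    mat.data = np.ones_like(mat.data)  # binarize repeated hits
    return CellByTileMatrix(mat, barcodes, tile_names, tile_size)


def tfidf_lsi(
    m: CellByTileMatrix,
    n_components: int = 30,
    top_tiles: int = 20_000,
    drop_first: bool = True,
    scale: float = 1e4,
    seed: int = 0,
) -> Embedding:
    """Single-pass TF-IDF + truncated SVD embedding.

    Tiles are ranked by cell frequency and the top ``top_tiles`` retained.
    TF is the row-normalized count, IDF = log(1 + n_cells / tile_frequency),
    the transform is log(1 + TF x IDF x scale), and components come from a
    seeded truncated SVD. The first component, which tracks per-cell depth,
    is dropped by default.
    """
    tile_freq = np.asarray(m.matrix.sum(axis=0)).ravel()
    order = np.argsort(-tile_freq, kind="stable")
    selected = order[: min(top_tiles, int((tile_freq > 0).sum()))]
    X = m.matrix[:, selected].astype(np.float64)

    max_rank = min(X.shape) - 1
    k = min(n_components + (1 if drop_first else 0), max_rank)
    if n_components >= min(X.shape):
        import warnings

        warnings.warn("rank-deficient matrix: returning fewer components", stacklevel=2)

    row_sums = np.asarray(X.sum(axis=1)).ravel()
    row_sums[row_sums == 0] = 1.0
    tf = sp.diags(1.0 / row_sums) @ X
    freq = np.asarray(X.sum(axis=0)).ravel()
    freq[freq == 0] = 1.0
    idf = np.log1p(X.shape[0] / freq)
    transformed = tf @ sp.diags(idf)
    transformed.data = np.log1p(transformed.data * scale)

    svd = TruncatedSVD(n_components=k, random_state=seed)
    coords = svd.fit_transform(transformed)
    if drop_first and coords.shape[1] > 1:
        coords = coords[:, 1:]
    return Embedding(coordinates=coords, barcodes=list(m.barcodes), dropped_first=drop_first)


def cluster_cells(
    e: Embedding,
    k_neighbors: int = 20,
    resolution: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """kNN graph (Euclidean) + Leiden modularity communities; labels 0..K-1."""
    n = e.coordinates.shape[0]
    if n < 3:
        raise ValueError("need at least 3 cells to cluster")
    k = min(k_neighbors, n - 1)
    nn = NearestNeighbors(n_neighbors=k).fit(e.coordinates)
    _, idx = nn.kneighbors(e.coordinates)
    edges = {(min(i, j), max(i, j)) for i in range(n) for j in idx[i, :] if i != j}
    graph = ig.Graph(n=n, edges=sorted(edges))
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
    )
    return np.asarray(part.membership)


def spike_in_evaluation(
    labels: Sequence[int],
    barcodes: Sequence[str],
    truth: Mapping[str, str],
    spike_label: str = "spike",
    recall_threshold: float = 0.8,
    purity_threshold: float = 0.5,
) -> SpikeInEntry:
    """Recall/purity of the spike population's modal cluster.

    recall = fraction of spike cells inside their modal cluster; purity =
    spike fraction of that cluster; success iff recall >= 0.8 and
    purity >= 0.5 (configurable).
    """
    labels = np.asarray(labels)
    is_spike = np.array([truth.get(b) == spike_label for b in barcodes])
    n_spike = int(is_spike.sum())
    if n_spike == 0:
        raise ValueError(f"no cells labelled {spike_label!r} in truth")
    spike_clusters = labels[is_spike]
    values, counts = np.unique(spike_clusters, return_counts=True)
    modal = values[np.argmax(counts)]
    recall = float(counts.max() / n_spike)
    cluster_size = int((labels == modal).sum())
    purity = float((spike_clusters == modal).sum() / cluster_size)
    return SpikeInEntry(
        n_spike=n_spike,
        n_clusters=int(labels.max()) + 1,
        majority_cluster_recall=recall,
        majority_cluster_purity=purity,
        success=recall >= recall_threshold and purity >= purity_threshold,
    )
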