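"""Founder-cell clustering and cross-limb distance statistics.

Founder cells are clustered from their pairwise lineage distances Δ with
Ward's minimum-variance method (Lance–Williams updates applied directly to
the given dissimilarities — Ward formally presumes squared Euclidean input;
applying it to Δ mirrors the procedure this module reproduces and is a
documented caveat).  The module also builds division-count window heat
maps and compares the Δ distributions of homologous vs non-homologous
founder pairs across two replicate limbs with a two-sample
Kolmogorov–Smirnov test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import ks_2samp

from .model import LineageForest, division_events

__all__ = [
    "Dendrogram",
    "ward_cluster",
    "cut_clusters",
    "to_newick",
    "WindowHeatmap",
    "division_count_windows",
    "HomologComparison",
    "homolog_distance_comparison",
]


@dataclass
class Dendrogram:
    """Agglomerative merge tree over founder cells.

    ``linkage`` is a scipy linkage matrix (merge pairs and heights);
    ``labels`` are the founder ids in input order.
    """

    linkage: np.ndarray
    labels: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]


def _as_square(matrix: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, list[str]]:
    if isinstance(matrix, pd.DataFrame):
        labels = [str(c) for c in matrix.columns]
        arr = matrix.to_numpy(dtype=float)
    else:
        arr = np.asarray(matrix, dtype=float)
        labels = [str(i) for i in range(arr.shape[0])]
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(arr, arr.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(arr) != 0):
        raise ValueError("distance matrix must have a zero diagonal")
    if np.any(arr < 0):
        raise ValueError("distances must be non-negative")
    return arr, labels


def ward_cluster(matrix: pd.DataFrame | np.ndarray) -> Dendrogram:
    """Ward hierarchical clustering of a symmetric Δ matrix."""
    arr, labels = _as_square(matrix)
    condensed = squareform(arr, checks=False)
    Z = hierarchy.linkage(condensed, method="ward")
    return Dendrogram(linkage=Z, labels=labels)


def cut_clusters(dendrogram: Dendrogram, k: int) -> np.ndarray:
    """Cut the merge sequence into ``k`` flat clusters (labels 1..k)."""
    if not 1 <= k <= dendrogram.n_leaves:
        raise ValueError(f"k={k} out of range [1, {dendrogram.n_leaves}]")
    return hierarchy.fcluster(dendrogram.linkage, t=k, criterion="maxclust")


def to_newick(dendrogram: Dendrogram) -> str:
    """Export a dendrogram as a Newick string with heights as branch lengths."""
    Z = dendrogram.linkage
    n = dendrogram.n_leaves
    heights = {i: 0.0 for i in range(n)}

    def node(i: int) -> str:
        if i < n:
            return dendrogram.labels[i]
        a, b, h, _ = Z[i - n]
        a, b = int(a), int(b)
        return (
            f"({node(a)}:{(h - heights[a]) / 2:.6g},"
            f"{node(b)}:{(h - heights[b]) / 2:.6g})"
        )

    for idx, (a, b, h, _) in enumerate(Z):
        heights[n + idx] = h
    return node(n + len(Z) - 1) + ";"


@dataclass
class WindowHeatmap:
    """Founders × time-windows matrix of division counts."""

    counts: pd.DataFrame
    edges: np.ndarray

    @property
    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)


def division_count_windows(
    forest: LineageForest,
    founder_ids: Sequence[int],
    n_windows: int,
    span: tuple[float, float],
) -> WindowHeatmap:
    """Count division events per founder subtree in equal-width time windows.

    ``span`` is (start, end) in hours; events exactly at the end boundary
    fall into the last window.  Row sums equal each founder's total number
    of divisions within the span.
    """
    t0, t1 = span
    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    if t1 <= t0:
        raise ValueError("empty time span")
    edges = np.linspace(t0, t1, n_windows + 1)
    rows = {}
    for fid in founder_ids:
        det = forest.get(fid)
        label = det.name or str(fid)
        times = [
            e.time_hours
            for e in division_events(forest, within=fid, strict=False)
            if t0 <= e.time_hours <= t1
        ]
        counts, _ = np.histogram(times, bins=edges)
        rows[label] = counts
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.columns = [f"[{edges[i]:g},{edges[i + 1]:g})" for i in range(n_windows)]
    return WindowHeatmap(counts=df, edges=edges)


@dataclass
class HomologComparison:
    """Homologous vs non-homologous Δ distributions across two limbs."""

    homolog: np.ndarray
    nonhomolog: np.ndarray
    homolog_pct: np.ndarray
    nonhomolog_pct: np.ndarray
    median_homolog_pct: float
    median_nonhomolog_pct: float
    ks_statistic: float
    p_value: float


def homolog_distance_comparison(cross_matrix: pd.DataFrame) -> HomologComparison:
    """Compare Δ of homologous vs non-homologous founder pairs across limbs.

    Rows index the founders of one limb, columns those of the other, both
    under the same identity vocabulary (e.g. parasegment+row+column names).
    Homologous values are the identity-matched entries, non-homologous all
    others.  Percent values express Δ relative to the batch maximum, so the
    medians are percentages of the largest observed distance.  The two
    samples are compared with a two-sided asymptotic Kolmogorov–Smirnov
    test.
    """
    common = [c for c in cross_matrix.index if c in set(cross_matrix.columns)]
    if not common:
        raise ValueError("no homologous founder pairs resolvable from the labels")
    arr = cross_matrix.to_numpy(dtype=float)
    homolog_mask = np.zeros(arr.shape, dtype=bool)
    col_pos = {c: i for i, c in enumerate(cross_matrix.columns)}
    row_pos = {r: i for i, r in enumerate(cross_matrix.index)}
    for label in common:
        homolog_mask[row_pos[label], col_pos[label]] = True
    homolog = arr[homolog_mask]
    nonhomolog = arr[~homolog_mask]
    max_delta = arr.max()
    scale = 100.0 / max_delta if max_delta > 0 else 0.0
    stat, p = ks_2samp(homolog, nonhomolog, method="asymp")
    return HomologComparison(
        homolog=homolog,
        nonhomolog=nonhomolog,
        homolog_pct=homolog * scale,
        nonhomolog_pct=nonhomolog * scale,
        median_homolog_pct=float(np.median(homolog * scale)),
        median_nonhomolog_pct=float(np.median(nonhomolog * scale)),
        ks_statistic=float(stat),
        p_value=float(p),
    )
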