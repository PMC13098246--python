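"""Hierarchical clustering of z-scored metabolite trajectories.

Reproduces the heatmap computation: metabolite rows are z-scored across time,
pairwise dissimilarity is the correlation distance (1 − Pearson r, range
[0, 2]), and rows are merged by unweighted average linkage (UPGMA).  Columns
(time) are never clustered — they stay chronological.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, leaves_list, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "ClusteredMatrix",
    "correlation_distance",
    "correlation_distance_matrix",
    "cluster_rows",
]


@dataclass
class ClusteredMatrix:
    """Z-score matrix with its UPGMA merge tree and leaf order."""

    matrix: pd.DataFrame          # metabolites × time, z-scores, original order
    leaf_order: list[str]         # metabolite ids in dendrogram leaf order
    linkage: np.ndarray           # scipy linkage matrix (n-1 × 4)

    def __post_init__(self) -> None:
        if sorted(self.leaf_order) != sorted(self.matrix.index):
            raise ValueError("leaf_order is not a permutation of the rows")
        heights = self.linkage[:, 2]
        if np.any(np.diff(heights) < -1e-12):
            raise ValueError("linkage heights must be non-decreasing")

    @property
    def ordered_matrix(self) -> pd.DataFrame:
        return self.matrix.loc[self.leaf_order]

    def cophenetic_matrix(self) -> np.ndarray:
        return squareform(cophenet(self.linkage))

    def to_tsv(self, path: str | Path, linkage_path: str | Path | None = None) -> None:
        """Write z-scores in leaf order; optionally the merge table."""
        self.ordered_matrix.to_csv(path, sep="\t")
        if linkage_path is not None:
            pd.DataFrame(
                self.linkage, columns=["merge_i", "merge_j", "height", "size"]
            ).to_csv(linkage_path, sep="\t", index=False)


def correlation_distance(x, y) -> float:
    """1 − Pearson correlation between two equal-length series (range [0, 2])."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("series must be 1-D, equal length and have ≥3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation distance is undefined for constant series")
    r = np.corrcoef(x, y)[0, 1]
    return float(1.0 - r)


def correlation_distance_matrix(matrix: pd.DataFrame) -> np.ndarray:
    """Condensed pairwise correlation-distance vector over the rows."""
    arr = matrix.to_numpy(dtype=float)
    n = arr.shape[0]
    out = []
    for i in range(n):
        for j in range(i + 1, n):
            out.append(correlation_distance(arr[i], arr[j]))
    return np.asarray(out)


def cluster_rows(matrix: pd.DataFrame | np.ndarray) -> ClusteredMatrix:
    """UPGMA over correlation distances between the rows of ``matrix``.

    Constant rows carry no trajectory information (their correlation is
    undefined) and are removed with a warning before clustering.  At least
    two usable rows are required.
    """
    if not isinstance(matrix, pd.DataFrame):
        matrix = pd.DataFrame(np.asarray(matrix, dtype=float))
    arr = matrix.to_numpy(dtype=float)
    keep = np.std(arr, axis=1) > 0
    if not keep.all():
        dropped = list(matrix.index[~keep])
        warnings.warn(f"removed constant rows before clustering: {dropped}",
                      stacklevel=2)
        matrix = matrix.loc[keep]
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 non-constant rows to cluster")
    dist = correlation_distance_matrix(matrix)
    # tiny negative distances from float cancellation clip to 0
    dist = np.maximum(dist, 0.0)
    link = linkage(dist, method="average")
    order = [matrix.index[i] for i in leaves_list(link)]
    return ClusteredMatrix(matrix=matrix, leaf_order=order, linkage=link)
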