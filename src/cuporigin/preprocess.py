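"""Probe filtering, standardization, group-wise centering and clustering.

Everything operates on a probes x samples log2 expression matrix
(`pandas.DataFrame`).  The IQR filter removes uninformative probes; the
mean-0 / variance-1 standardization and within-group centering prepare
matrices for clustering, enrichment and instability scoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist


def iqr_filter(matrix: pd.DataFrame, threshold: float = 0.8) -> pd.DataFrame:
    """Keep probes whose across-sample interquartile range is >= threshold.

    Quartiles use linear interpolation between order statistics.  A
    threshold of 0 is the identity; 0.8 is the conventional setting for
    RMA-normalized arrays.
    """
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0 (got {threshold})")
    if threshold == 0:
        return matrix
    values = matrix.to_numpy(dtype=float)
    q1, q3 = np.percentile(values, [25, 75], axis=1, method="linear")
    return matrix.loc[(q3 - q1) >= threshold]


def standardize_probes(matrix: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Scale every probe row to mean 0, variance 1.

    Raises on zero-variance probes (they carry no information and
    would divide by zero); run :func:`iqr_filter` first to drop them.
    """
    values = matrix.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=ddof, keepdims=True)
    zero = np.flatnonzero(sd.ravel() == 0)
    if zero.size:
        raise ValueError(f"zero-variance probe {matrix.index[zero[0]]!r}")
    return pd.DataFrame((values - mean) / sd, index=matrix.index, columns=matrix.columns)


def center_within_groups(matrix: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Subtract, per probe, the mean over each group of samples.

    After the call every probe has mean 0 inside every group, so only
    within-group structure remains — the usual preparation before
    comparing groups that sit in different tumor classes.
    """
    groups = groups.reindex(matrix.columns)
    if groups.isna().any():
        missing = matrix.columns[groups.isna()][0]
        raise ValueError(f"sample {missing!r} has no group label")
    out = matrix.to_numpy(dtype=float).copy()
    for _, cols in groups.groupby(groups).groups.items():
        j = matrix.columns.get_indexer(cols)
        out[:, j] -= out[:, j].mean(axis=1, keepdims=True)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


@dataclass(frozen=True)
class Dendrogram:
    """Average-linkage tree: scipy linkage matrix plus leaf labels."""

    merges: np.ndarray  # scipy (n-1) x 4 linkage matrix
    labels: tuple[str, ...]

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def to_newick(self) -> str:
        """Serialize as a Newick string with ultrametric branch lengths
        (node height = merge height / 2, as usual for UPGMA)."""
        from scipy.cluster.hierarchy import to_tree

        root = to_tree(self.merges)

        def walk(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            height = node.dist / 2
            parts = [
                f"{walk(child)}:{height - child.dist / 2:.6g}"
                for child in (node.left, node.right)
            ]
            return "(" + ",".join(parts) + ")"

        return walk(root) + ";"


def average_linkage_cluster(
    matrix: pd.DataFrame,
    axis: str = "rows",
    distance: str = "euclidean",
) -> Dendrogram:
    """UPGMA (average linkage) clustering of probes or samples.

    ``distance`` is ``euclidean`` or ``correlation`` (1 - Pearson r).
    Merge heights of UPGMA are non-decreasing.
    """
    if axis not in ("rows", "columns"):
        raise ValueError("axis must be 'rows' or 'columns'")
    if distance not in ("euclidean", "correlation"):
        raise ValueError("distance must be 'euclidean' or 'correlation'")
    data = matrix.to_numpy(dtype=float)
    labels = tuple(matrix.index) if axis == "rows" else tuple(matrix.columns)
    if axis == "columns":
        data = data.T
    if len(labels) < 2:
        raise ValueError("need at least 2 items to cluster")
    merges = linkage(pdist(data, metric=distance), method="average")
    return Dendrogram(merges=merges, labels=labels)
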