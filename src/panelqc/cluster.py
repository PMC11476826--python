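"""Hierarchical clustering of samples on panel-restricted log-TPM.

Samples are compared with correlation distance d = 1 − Pearson r (not
1 − R²: anticorrelated samples should be maximally distant, which squaring
would conflate with perfect agreement) and merged by average linkage.  The
resulting dendrogram can be exported as Newick with ultrametric branch
lengths (leaf-to-merge height = merge distance / 2).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import DegenerateInputError
from .matrix import ExpressionMatrix
from .panel import GenePanel, subset_matrix


def distance_matrix(
    matrix: ExpressionMatrix, panel: GenePanel | None = None
) -> pd.DataFrame:
    """Pairwise correlation distance 1 − r between samples on panel genes."""
    if matrix.unit != "logTPM":
        raise ValueError(f"clustering needs logTPM, got {matrix.unit!r}")
    if matrix.n_samples < 2:
        raise ValueError("need at least 2 samples")
    sub = subset_matrix(matrix, panel) if panel is not None else matrix
    arr = sub.values.to_numpy(dtype=float)
    if np.any(np.ptp(arr, axis=0) == 0):
        bad = [s for s, c in zip(sub.sample_ids, arr.T) if np.ptp(c) == 0]
        raise DegenerateInputError(f"constant sample vector(s): {bad[:5]}")
    r = np.corrcoef(arr, rowvar=False)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # enforce exact symmetry against float jitter
    return pd.DataFrame(d, index=sub.sample_ids, columns=sub.sample_ids)


@dataclass
class Dendrogram:
    """Binary merge tree over sample leaves (scipy linkage encoding)."""

    linkage_matrix: np.ndarray
    labels: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]


def hierarchical_cluster(dist: pd.DataFrame, linkage: str = "average") -> Dendrogram:
    """Agglomerative clustering of a symmetric distance matrix.

    Ties are resolved deterministically by scipy's ordering (lowest
    cluster indices merge first among equals).
    """
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    labels = (
        [str(c) for c in dist.columns]
        if isinstance(dist, pd.DataFrame)
        else [str(i) for i in range(d.shape[0])]
    )
    condensed = squareform(d, checks=False)
    Z = hierarchy.linkage(condensed, method=linkage)
    return Dendrogram(linkage_matrix=Z, labels=labels)


# underscores must be quoted too: unquoted Newick labels read "_" as a space
_NEEDS_QUOTE = re.compile(r"[\s()\[\]:;,'_]")


def _quote_label(label: str) -> str:
    if _NEEDS_QUOTE.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(dendrogram: Dendrogram) -> str:
    """Newick string with ultrametric branch lengths (height = dist / 2)."""
    tree = hierarchy.to_tree(dendrogram.linkage_matrix)

    def height(node) -> float:
        return 0.0 if node.is_leaf() else node.dist / 2.0

    def render(node, parent_height: float) -> str:
        bl = parent_height - height(node)
        if node.is_leaf():
            return f"{_quote_label(dendrogram.labels[node.id])}:{bl:.10g}"
        left = render(node.left, height(node))
        right = render(node.right, height(node))
        return f"({left},{right}):{bl:.10g}"

    h = height(tree)
    if tree.is_leaf():
        return f"{_quote_label(dendrogram.labels[tree.id])}:0;"
    left = render(tree.left, h)
    right = render(tree.right, h)
    return f"({left},{right});"


def write_newick(dendrogram: Dendrogram, path) -> None:
    with open(path, "w") as fh:
        fh.write(to_newick(dendrogram) + "\n")


def nearest_neighbors(dist: pd.DataFrame) -> pd.Series:
    """Each sample's nearest other sample under the distance matrix."""
    d = dist.copy()
    np.fill_diagonal(d.values, np.inf)
    return d.idxmin(axis=1)
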