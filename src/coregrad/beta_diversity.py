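"""Unweighted UniFrac over a rooted phylogeny, and principal coordinates analysis.

Unweighted UniFrac between two communities is the fraction of tree branch
length leading only to leaves present in exactly one of them:

    d(A, B) = sum(edge lengths marked by exactly one of A, B)
              / sum(edge lengths marked by at least one)

where an edge is "marked" by a community when any leaf below it is present.
The rooted convention is used: edges above the union's most recent common
ancestor still count when marked.  Because presence/absence only enters, the
distance is invariant to sequencing depth.

PCoA embeds a distance matrix by Gower double-centering B = -1/2 J D^2 J and
eigendecomposition; coordinates are eigenvectors scaled by sqrt(lambda) for
positive eigenvalues.  Negative eigenvalues (non-Euclidean distances) are
reported but excluded both from the coordinates and from the variance
denominator — the convention of the ordination software lineage common in
amplicon work; no Lingoes/Cailliez correction is applied by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
import skbio

from coregrad.data_model import FeatureTable


def _tree_edges(tree: skbio.TreeNode) -> tuple[np.ndarray, np.ndarray, dict[str, int]]:
    """Decompose a rooted tree into (edge lengths, edge×leaf incidence, leaf index).

    One edge per non-root node (the branch to its parent); incidence[e, l] is
    True when leaf l is a descendant of edge e's child node.  Missing branch
    lengths count as 0.
    """
    leaves = [leaf.name for leaf in tree.tips()]
    leaf_index = {name: i for i, name in enumerate(leaves)}
    lengths: list[float] = []
    rows: list[np.ndarray] = []
    below: dict[int, np.ndarray] = {}
    for node in tree.postorder(include_self=False):
        if node.is_tip():
            mask = np.zeros(len(leaves), dtype=bool)
            mask[leaf_index[node.name]] = True
        else:
            mask = np.zeros(len(leaves), dtype=bool)
            for child in node.children:
                mask |= below[id(child)]
        below[id(node)] = mask
        lengths.append(float(node.length or 0.0))
        rows.append(mask)
    return np.asarray(lengths), np.asarray(rows), leaf_index


def unweighted_unifrac_pair(
    presence_a: Iterable[str], presence_b: Iterable[str], tree: skbio.TreeNode
) -> float:
    """Unweighted UniFrac between two feature sets on a rooted tree."""
    set_a, set_b = set(presence_a), set(presence_b)
    lengths, incidence, leaf_index = _tree_edges(tree)
    missing = sorted((set_a | set_b) - set(leaf_index))
    if missing:
        raise ValueError(f"features not on the tree: {missing}")
    if not (set_a | set_b):
        raise ValueError("the union of the two communities is empty")
    mask_a = np.zeros(len(leaf_index), dtype=bool)
    mask_b = np.zeros(len(leaf_index), dtype=bool)
    mask_a[[leaf_index[f] for f in set_a]] = True
    mask_b[[leaf_index[f] for f in set_b]] = True
    marked_a = incidence @ mask_a > 0
    marked_b = incidence @ mask_b > 0
    union = lengths[marked_a | marked_b].sum()
    if union == 0:
        return 0.0
    unique = lengths[marked_a ^ marked_b].sum()
    return float(unique / union)


def unifrac_matrix(table: FeatureTable, tree: skbio.TreeNode) -> skbio.DistanceMatrix:
    """Pairwise unweighted UniFrac over all samples of a feature table.

    Counts are reduced to presence/absence (count > 0).  Every feature in the
    table must be a leaf of the tree; tree leaves absent from the table are
    simply never marked.
    """
    lengths, incidence, leaf_index = _tree_edges(tree)
    missing = [f for f in table.feature_ids if f not in leaf_index]
    if missing:
        raise ValueError(f"table features not on the tree: {missing}")
    presence = table.counts > 0
    empty = [s for s, ok in zip(table.sample_ids, presence.any(axis=0)) if not ok]
    if empty:
        raise ValueError(f"samples with no features present: {empty}")
    # project sample presence onto tree-leaf order
    n_leaves = len(leaf_index)
    leaf_presence = np.zeros((n_leaves, len(table.sample_ids)), dtype=bool)
    row_of = [leaf_index[f] for f in table.feature_ids]
    leaf_presence[row_of, :] = presence
    marked = incidence @ leaf_presence > 0  # edges × samples
    weighted = marked * lengths[:, None]
    shared = weighted.T @ marked  # sum of lengths marked by both samples
    total = weighted.sum(axis=0)
    union = total[:, None] + total[None, :] - shared
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = np.where(union > 0, (union - shared) / union, 0.0)
    dist = (dist + dist.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    return skbio.DistanceMatrix(dist, ids=table.sample_ids)


@dataclass(frozen=True)
class OrdinationResult:
    """PCoA output: sample coordinates, eigenvalues, variance fractions.

    `eigenvalues` holds the full spectrum in non-increasing order (negative
    values included for diagnostics); `coordinates` and
    `proportion_explained` cover only the retained positive axes.
    """

    coordinates: pd.DataFrame  # samples × axes
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]


def pcoa(dm: skbio.DistanceMatrix, n_axes: int | None = None) -> OrdinationResult:
    """Principal coordinates analysis via Gower double-centering."""
    d = np.asarray(dm.data, dtype=float)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    b = (b + b.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(abs(eigvals[0]), abs(eigvals[-1]), 1.0) * 1e-12 if n else 0.0
    positive = eigvals > tol
    n_pos = int(positive.sum())
    if n_axes is None:
        n_axes = n_pos
    if n_axes > max(n - 1, 0):
        warnings.warn(f"n_axes={n_axes} clipped to n-1={n - 1}")
        n_axes = max(n - 1, 0)
    n_keep = min(n_axes, n_pos)
    coords = eigvecs[:, :n_keep] * np.sqrt(eigvals[:n_keep])
    denom = eigvals[positive].sum()
    if denom > 0:
        proportions = eigvals[:n_keep] / denom
    else:
        proportions = np.zeros(n_keep)
    frame = pd.DataFrame(
        coords, index=list(dm.ids), columns=[f"PC{i + 1}" for i in range(n_keep)]
    )
    frame.index.name = "sample_id"
    return OrdinationResult(
        coordinates=frame, eigenvalues=eigvals, proportion_explained=proportions
    )
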