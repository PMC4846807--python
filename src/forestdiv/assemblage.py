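"""Assemblage structure: group-average clustering and correspondence analysis.

Works on a stand x species abundance matrix. Stands are compared by
Bray-Curtis dissimilarity (or chi-square distance, for consistency with the
ordination), agglomerated by the group-average (UPGMA) criterion, and cut
into k groups; correspondence analysis (CA) ordinates the same matrix by a
singular value decomposition of the chi-square standardized residuals, so
the total inertia equals the Pearson chi-square statistic divided by the
grand total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .plot_data import AbundanceTable

__all__ = [
    "StandDistanceMatrix",
    "StandOrdination",
    "stand_distance",
    "upgma",
    "cut_groups",
    "dendrogram_to_newick",
    "correspondence_analysis",
]


@dataclass
class StandDistanceMatrix:
    labels: list[str]
    matrix: np.ndarray  # square symmetric, zero diagonal
    metric: str

    def condensed(self) -> np.ndarray:
        return squareform(self.matrix, checks=False)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)


@dataclass
class StandOrdination:
    """CA solution: row/column scores (symmetric scaling) and inertia."""

    row_scores: pd.DataFrame  # stands x axes
    col_scores: pd.DataFrame  # species x axes
    eigenvalues: np.ndarray
    total_inertia: float

    @property
    def inertia_fraction(self) -> np.ndarray:
        return self.eigenvalues / self.total_inertia


def _stand_matrix(abundance: AbundanceTable | pd.DataFrame) -> pd.DataFrame:
    """Stand x species orientation (units as rows)."""
    if isinstance(abundance, AbundanceTable):
        return abundance.counts.T.astype(float)
    return abundance.astype(float)


def stand_distance(abundance: AbundanceTable | pd.DataFrame, metric: str = "braycurtis") -> StandDistanceMatrix:
    """Pairwise dissimilarities between stands.

    ``braycurtis`` (default) on raw abundances, in [0, 1]; ``chisq`` is the
    chi-square distance between row profiles, the metric implicit in CA.
    """
    X = _stand_matrix(abundance)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 stands")
    rowsum = X.sum(axis=1).to_numpy()
    if (rowsum == 0).any():
        bad = list(X.index[rowsum == 0])
        raise ValueError(f"stands with zero total abundance: {bad}")

    A = X.to_numpy()
    if metric == "braycurtis":
        from scipy.spatial.distance import pdist

        d = squareform(pdist(A, metric="braycurtis"))
    elif metric == "chisq":
        total = A.sum()
        colsum = A.sum(axis=0)
        keep = colsum > 0
        prof = A[:, keep] / A.sum(axis=1, keepdims=True)
        w = total / colsum[keep]
        diff = prof[:, None, :] - prof[None, :, :]
        d = np.sqrt(np.einsum("ijk,k->ij", diff**2, w))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    np.fill_diagonal(d, 0.0)
    return StandDistanceMatrix(labels=list(X.index), matrix=d, metric=metric)


def upgma(dist: StandDistanceMatrix) -> np.ndarray:
    """Group-average (UPGMA) agglomeration; returns a scipy linkage matrix.

    Deterministic: ties resolve to the earliest pair in the nearest-neighbor
    chain ordering used by scipy's average-linkage implementation.
    """
    return linkage(dist.condensed(), method="average")


def cut_groups(Z: np.ndarray, labels: list[str], k: int = 2) -> pd.Series:
    """Flat group labels (1..k) from a linkage matrix."""
    assignment = fcluster(Z, t=k, criterion="maxclust")
    return pd.Series(assignment, index=labels, name="group")


def dendrogram_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Serialize a linkage matrix as a Newick tree with branch lengths."""
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}
    nodes = {i: labels[i] for i in range(n)}
    for i, (a, b, h, _) in enumerate(Z):
        a, b = int(a), int(b)
        la = h / 2.0 - heights[a] / 2.0
        lb = h / 2.0 - heights[b] / 2.0
        nodes[n + i] = f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g})"
        heights[n + i] = h
    return nodes[n + len(Z) - 1] + ";"


def correspondence_analysis(abundance: AbundanceTable | pd.DataFrame) -> StandOrdination:
    """Correspondence analysis of a stand x species contingency table.

    SVD of D_r^{-1/2} (P - r c^T) D_c^{-1/2} with P the relative-frequency
    matrix and r, c its margins. Eigenvalues are squared singular values;
    their sum (total inertia) equals chi-square / grand total. Scores are
    reported in symmetric scaling: D^{-1/2} U Sigma^{1/2}.
    """
    X = _stand_matrix(abundance)
    A = X.to_numpy()
    if (A < 0).any():
        raise ValueError("abundances must be nonnegative")
    if (A.sum(axis=1) == 0).any() or (A.sum(axis=0) == 0).any():
        raise ValueError("drop all-zero rows/columns before CA")

    total = A.sum()
    P = A / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)

    keep = sv > 1e-12  # rank deficiency yields fewer axes, not failure
    U, sv, Vt = U[:, keep], sv[keep], Vt[keep, :]
    eig = sv**2
    axes = [f"CA{i + 1}" for i in range(sv.size)]
    row = (U * np.sqrt(sv)) / np.sqrt(r)[:, None]
    col = (Vt.T * np.sqrt(sv)) / np.sqrt(c)[:, None]
    return StandOrdination(
        row_scores=pd.DataFrame(row, index=X.index, columns=axes),
        col_scores=pd.DataFrame(col, index=X.columns, columns=axes),
        eigenvalues=eig,
        total_inertia=float(eig.sum()),
    )
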