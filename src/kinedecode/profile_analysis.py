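"""Comparing importance profiles: correlation, clustering, embedding."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "ProfileSet",
    "CorrelationResult",
    "DendrogramResult",
    "EmbeddingResult",
    "profile_spearman",
    "spearman_matrix",
    "ward_dendrogram",
    "mds_embed",
    "rating_dendrogram",
]


@dataclass
class ProfileSet:
    """P row vectors (importance profiles or rating vectors) with labels."""

    profiles: np.ndarray  # (P, J)
    row_labels: list[str]

    def __post_init__(self) -> None:
        self.profiles = np.asarray(self.profiles, dtype=float)
        if self.profiles.ndim != 2 or self.profiles.shape[0] < 2:
            raise ValueError("need a 2-D matrix with at least 2 rows")
        if len(self.row_labels) != self.profiles.shape[0]:
            raise ValueError("one label per row required")
        if not np.isfinite(self.profiles).all():
            raise ValueError("missing entries in profile set")


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    n: int


def profile_spearman(p, q) -> CorrelationResult:
    """Spearman rank correlation (average ranks for ties), two-sided p."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape or p.ndim != 1 or p.size < 3:
        raise ValueError("need equal-length 1-D profiles of at least 3 entries")
    if np.ptp(p) == 0 or np.ptp(q) == 0:
        raise ValueError("constant profile: ranks are degenerate")
    res = stats.spearmanr(p, q)
    return CorrelationResult(r=float(res.statistic), p_value=float(res.pvalue), n=p.size)


def spearman_matrix(pset: ProfileSet) -> pd.DataFrame:
    """All pairwise Spearman correlations as a labelled square table."""
    P = pset.profiles.shape[0]
    out = np.eye(P)
    for i in range(P):
        for j in range(i + 1, P):
            out[i, j] = out[j, i] = profile_spearman(pset.profiles[i], pset.profiles[j]).r
    return pd.DataFrame(out, index=pset.row_labels, columns=pset.row_labels)


@dataclass
class DendrogramResult:
    merges: np.ndarray  # scipy linkage matrix (P-1, 4)
    leaf_labels: list[str]
    linkage_method: str = "ward"
    distance: str = "euclidean"

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def cut(self, n_clusters: int) -> np.ndarray:
        """Flat cluster labels (0-based) for a cut into ``n_clusters``."""
        from scipy.cluster.hierarchy import fcluster

        return fcluster(self.merges, t=n_clusters, criterion="maxclust") - 1


def ward_dendrogram(pset: ProfileSet) -> DendrogramResult:
    """Agglomerative merge sequence under Ward's criterion on Euclidean distance."""
    merges = linkage(pset.profiles, method="ward", metric="euclidean")
    return DendrogramResult(merges=merges, leaf_labels=list(pset.row_labels))


def rating_dendrogram(ratings: pd.DataFrame) -> DendrogramResult:
    """Ward/Euclidean dendrogram over rating columns (genres as leaves)."""
    values = ratings.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("missing ratings")
    pset = ProfileSet(profiles=values.T, row_labels=[str(c) for c in ratings.columns])
    return ward_dendrogram(pset)


@dataclass
class EmbeddingResult:
    coordinates: np.ndarray  # (P, ndim), column-centred
    stress: float  # residual distance misfit, >= 0
    eigenvalues: np.ndarray


def mds_embed(pset: ProfileSet, ndim: int = 3) -> EmbeddingResult:
    """Classical (Torgerson) metric MDS of the Euclidean dissimilarities.

    Deterministic up to axis reflection; coordinates are centred by
    construction of the double-centred Gram matrix.
    """
    P = pset.profiles.shape[0]
    if P <= ndim:
        raise ValueError(f"need more than {ndim} profiles for a {ndim}-D embedding")
    D2 = squareform(pdist(pset.profiles, metric="sqeuclidean"))
    J = np.eye(P) - np.ones((P, P)) / P
    B = -0.5 * J @ D2 @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    top = np.clip(eigval[:ndim], 0.0, None)
    coords = eigvec[:, :ndim] * np.sqrt(top)
    d_in = squareform(np.sqrt(np.maximum(D2, 0.0)))
    d_out = pdist(coords)
    denom = float(np.sum(d_in**2))
    stress = float(np.sqrt(np.sum((d_in - d_out) ** 2) / denom)) if denom > 0 else 0.0
    return EmbeddingResult(coordinates=coords, stress=stress, eigenvalues=eigval)
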