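"""Ordination, diversity and clustering for microbial community matrices.

Implements the community-structure toolkit used throughout the pipeline:
chord transformation (rows scaled to unit Euclidean norm, so Euclidean
distance becomes chord distance), PCA on the centered but unscaled matrix,
Bray-Curtis dissimilarity, classical-scaling PCoA, Hill-number diversity
(the effective number of equally abundant phylotypes), and classic UPGMA
clustering with an ultrametric dendrogram.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "OrdinationResult",
    "DistanceMatrix",
    "DiversityResult",
    "Dendrogram",
    "chord_transform",
    "pca",
    "bray_curtis",
    "pcoa",
    "hill_diversity",
    "upgma",
]


@dataclass
class OrdinationResult:
    """Scores and variance decomposition from PCA or PCoA.

    ``explained`` fractions are of total variance for PCA and of the
    positive-eigenvalue sum for PCoA.  ``loadings`` (OTU weights per axis)
    are available for PCA only.
    """

    scores: np.ndarray  # samples x axes
    explained: np.ndarray
    eigenvalues: np.ndarray  # all eigenvalues, including negatives for PCoA
    method: str
    sample_ids: list[str] | None = None
    loadings: np.ndarray | None = None  # features x axes (PCA only)


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(d < 0):
            raise ValueError("distances must be non-negative")
        self.d = d


@dataclass
class DiversityResult:
    q: float
    values: np.ndarray  # per-sample effective number of phylotypes
    sample_ids: list[str] | None = None


def chord_transform(rel_abund: np.ndarray) -> np.ndarray:
    """Scale each row to unit Euclidean norm (the chord transformation)."""
    x = np.asarray(rel_abund, dtype=float)
    if np.any(x < 0):
        raise ValueError("abundances must be non-negative")
    norms = np.linalg.norm(x, axis=1)
    if np.any(norms == 0):
        raise ValueError(f"all-zero row at index {int(np.argmax(norms == 0))}")
    return x / norms[:, None]


def pca(matrix: np.ndarray, n_axes: int, sample_ids: list[str] | None = None) -> OrdinationResult:
    """PCA on the column-centered (not variance-scaled) matrix.

    Scores are projections onto the top eigenvectors of the covariance
    matrix; ``explained[i]`` is the i-th eigenvalue over the eigenvalue sum.
    Sign convention: each axis is flipped so its largest-magnitude loading
    is positive, making runs comparable across platforms.
    """
    x = np.asarray(matrix, dtype=float)
    n, p = x.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 rows")
    max_axes = min(n - 1, p)
    if n_axes > max_axes:
        raise ValueError(f"n_axes={n_axes} exceeds min(n-1, p)={max_axes}")
    xc = x - x.mean(axis=0)
    # SVD of the centered matrix: eigenvalues of the covariance are s^2/(n-1).
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    eigvals = s**2 / (n - 1)
    total = eigvals.sum()
    loadings = vt.T[:, :n_axes]
    scores = xc @ loadings
    for k in range(n_axes):
        j = int(np.argmax(np.abs(loadings[:, k])))
        if loadings[j, k] < 0:
            loadings[:, k] = -loadings[:, k]
            scores[:, k] = -scores[:, k]
    explained = eigvals[:n_axes] / total if total > 0 else np.zeros(n_axes)
    return OrdinationResult(
        scores=scores,
        explained=explained,
        eigenvalues=eigvals,
        method="pca_chord",
        sample_ids=sample_ids,
        loadings=loadings,
    )


def bray_curtis(matrix: np.ndarray, labels: list[str] | None = None) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarities: 1 - 2*sum(min)/(sum_x + sum_y)."""
    x = np.asarray(matrix, dtype=float)
    if np.any(x < 0):
        raise ValueError("Bray-Curtis requires non-negative abundances")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        d = squareform(pdist(x, metric="braycurtis"))
    if np.isnan(d).any():
        warnings.warn("all-zero row pair: Bray-Curtis set to 0 by convention", stacklevel=2)
        d = np.nan_to_num(d, nan=0.0)
    if labels is None:
        labels = [str(i) for i in range(x.shape[0])]
    return DistanceMatrix(labels=labels, d=d)


def pcoa(dist: DistanceMatrix, n_axes: int) -> OrdinationResult:
    """Principal coordinate analysis (classical scaling) of a distance matrix.

    Double-centers -D^2/2, eigendecomposes, and scales eigenvectors by the
    square root of their (positive) eigenvalues.  Negative eigenvalues are
    reported in ``eigenvalues`` but excluded from axes and from the
    ``explained`` denominator; no Cailliez/Lingoes correction is applied.
    """
    d = dist.d
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > max(1e-10 * abs(eigvals[0]), 1e-12) if eigvals[0] > 0 else eigvals > 0
    n_pos = int(pos.sum())
    if n_axes > n_pos:
        warnings.warn(
            f"requested {n_axes} axes but only {n_pos} positive eigenvalues; "
            "returning all available axes",
            stacklevel=2,
        )
        n_axes = n_pos
    scores = eigvecs[:, :n_axes] * np.sqrt(eigvals[:n_axes])
    for k in range(n_axes):
        i = int(np.argmax(np.abs(scores[:, k])))
        if scores[i, k] < 0:
            scores[:, k] = -scores[:, k]
    pos_sum = eigvals[pos].sum()
    explained = eigvals[:n_axes] / pos_sum if pos_sum > 0 else np.zeros(n_axes)
    return OrdinationResult(
        scores=scores,
        explained=explained,
        eigenvalues=eigvals,
        method="pcoa_bray",
        sample_ids=dist.labels,
    )


def hill_diversity(rel_abund: np.ndarray, q: float = 2.0,
                   sample_ids: list[str] | None = None) -> DiversityResult:
    """Hill number of order q: the effective number of phylotypes per sample.

    qD = (sum_i p_i^q)^(1/(1-q)); q=1 is the exponential-Shannon limit
    exp(-sum p ln p); q=2 is the inverse Simpson concentration 1/sum(p^2).
    Zero-abundance phylotypes are excluded from the sums.
    """
    x = np.asarray(rel_abund, dtype=float)
    if np.any(x < 0):
        raise ValueError("relative abundances must be non-negative")
    if not np.allclose(x.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("rows must sum to 1")
    if q < 0:
        raise ValueError("q must be >= 0")
    values = np.empty(x.shape[0])
    for i, row in enumerate(x):
        p = row[row > 0]
        if abs(q - 1.0) < 1e-12:
            values[i] = np.exp(-np.sum(p * np.log(p)))
        else:
            values[i] = np.sum(p**q) ** (1.0 / (1.0 - q))
    return DiversityResult(q=q, values=values, sample_ids=sample_ids)


# ---------------------------------------------------------------------------
# UPGMA

@dataclass
class Dendrogram:
    """UPGMA tree: newick string plus a scipy-style merge table.

    ``merges`` rows are (node_a, node_b, height, size): leaf indices are
    0..n-1, internal node i is numbered n+i; height is the ultrametric
    height of the merge node (average inter-cluster distance / 2).
    """

    newick: str
    merges: np.ndarray
    labels: list[str]

    def cophenetic(self) -> np.ndarray:
        """Cophenetic distance matrix (2x merge height of the join node)."""
        n = len(self.labels)
        members: dict[int, list[int]] = {i: [i] for i in range(n)}
        coph = np.zeros((n, n))
        for k, (a, b, h, _) in enumerate(self.merges):
            ma, mb = members.pop(int(a)), members.pop(int(b))
            for i in ma:
                for j in mb:
                    coph[i, j] = coph[j, i] = 2 * h
            members[n + k] = ma + mb
        return coph


def upgma(dist: DistanceMatrix) -> Dendrogram:
    """Classic UPGMA: size-weighted average-linkage agglomeration.

    Each merge node sits at height = (average pairwise distance between the
    two clusters) / 2, so the output is ultrametric.  Ties are broken by the
    lexicographically lowest (i, j) pair of current cluster indices, where
    clusters are ordered by creation (leaves first, in label order).
    """
    n = len(dist.labels)
    if n < 2:
        raise ValueError("UPGMA needs at least 2 samples")
    # active clusters: id -> (size, height, newick)
    active: dict[int, tuple[int, float, str]] = {
        i: (1, 0.0, dist.labels[i]) for i in range(n)
    }
    d: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            d[(i, j)] = dist.d[i, j]
    merges = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        ids = sorted(active)
        best = None
        for a_idx in range(len(ids)):
            for b_idx in range(a_idx + 1, len(ids)):
                a, b = ids[a_idx], ids[b_idx]
                dv = d[(a, b)]
                if best is None or dv < best[0] - 1e-15:
                    best = (dv, a, b)
        dv, a, b = best
        size_a, h_a, nw_a = active.pop(a)
        size_b, h_b, nw_b = active.pop(b)
        height = dv / 2.0
        nw = f"({nw_a}:{height - h_a:.10g},{nw_b}:{height - h_b:.10g})"
        # size-weighted average linkage update (equivalent to recomputing the
        # mean over all raw inter-cluster pairs)
        for c in list(active):
            key_ac = (min(a, c), max(a, c))
            key_bc = (min(b, c), max(b, c))
            d_new = (size_a * d.pop(key_ac) + size_b * d.pop(key_bc)) / (size_a + size_b)
            d[(min(next_id, c), max(next_id, c))] = d_new
        merges[step] = (a, b, height, size_a + size_b)
        active[next_id] = (size_a + size_b, height, nw)
        next_id += 1
    (_, _, nw) = next(iter(active.values()))
    return Dendrogram(newick=nw + ";", merges=merges, labels=list(dist.labels))
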