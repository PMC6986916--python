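"""Similarity graph, Laplacians and kernel matrix over variable pairs.

The m pair-feature vectors are compared with a squared-exponential
similarity W[k,k'] = exp(-||x_k - x_k'||^2 / (2 sigma1^2)), from which the
(normalized) graph Laplacian encodes the manifold-smoothness penalty of the
transductive classifier. The Mercer kernel K has the same functional form
with its own length scale sigma2, which defaults to sigma1. Length scales
are estimated as the average distance to the nearest k_neighbors feature
vectors, over a random subsample of rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform

from .pair_featurization import PairFeatureMatrix

# floor on degrees before D^(-1/2): guards underflow when all similarities
# are vanishingly small relative to sigma1
_DEGREE_FLOOR = 1e-300


@dataclass
class KernelMatrix:
    """Mercer kernel evaluated at all m pairs, with the L/U partition.

    Rows/columns are ordered labelled-first: indices [0, m_labelled) are the
    labelled pairs, the rest unlabelled.
    """

    K_full: np.ndarray
    m_labelled: int

    def __post_init__(self) -> None:
        self.K_full = np.asarray(self.K_full, dtype=float)
        m = self.K_full.shape[0]
        if self.K_full.shape != (m, m):
            raise ValueError("kernel matrix must be square")
        if not 0 <= self.m_labelled <= m:
            raise ValueError("m_labelled out of range")

    @property
    def m(self) -> int:
        return self.K_full.shape[0]

    @property
    def m_unlabelled(self) -> int:
        return self.m - self.m_labelled

    @property
    def K_UK(self) -> np.ndarray:
        """Unlabelled-rows slice (m_U x m)."""
        return self.K_full[self.m_labelled:, :]

    @property
    def K_LK(self) -> np.ndarray:
        """Labelled-rows slice (m_L x m)."""
        return self.K_full[: self.m_labelled, :]


@dataclass
class ManifoldGraph:
    """Similarity matrix with its derived degree/Laplacian structure."""

    W: np.ndarray
    degrees: np.ndarray
    L: np.ndarray
    L_norm: np.ndarray
    sigma1: float
    sigma2: float


def estimate_length_scale(
    feats: PairFeatureMatrix | np.ndarray,
    k_neighbors: int = 50,
    subsample_size: int = 1000,
    seed: int = 0,
) -> float:
    """Average distance to the nearest k_neighbors rows, over a subsample.

    For each of min(subsample_size, m) uniformly sampled rows the Euclidean
    distances to all other rows are computed, the min(k_neighbors, m-1)
    smallest are averaged (self-distance excluded), and the result is
    averaged over the subsample. Raises when the scale comes out zero (all
    rows identical): supply sigma explicitly in that case.
    """
    X = feats.features if isinstance(feats, PairFeatureMatrix) else np.asarray(feats)
    m = X.shape[0]
    if m < 2:
        raise ValueError("need at least 2 feature rows to estimate a scale")
    if k_neighbors < 1 or subsample_size < 1:
        raise ValueError("k_neighbors and subsample_size must be positive")
    k = min(k_neighbors, m - 1)
    rng = np.random.default_rng(seed)
    if subsample_size < m:
        rows = rng.choice(m, size=subsample_size, replace=False)
    else:
        rows = np.arange(m)
    dists = cdist(X[rows], X)
    dists[np.arange(len(rows)), rows] = np.inf  # exclude self
    part = np.partition(dists, k - 1, axis=1)[:, :k]
    scale = float(part.mean())
    if scale == 0.0:
        raise ValueError(
            "all feature rows are identical (estimated scale 0); "
            "supply sigma explicitly"
        )
    return scale


def similarity_matrix(
    feats: PairFeatureMatrix | np.ndarray, sigma1: float
) -> np.ndarray:
    """Squared-exponential similarity of all feature rows.

    W[k,k'] = exp(-||x_k - x_k'||_2^2 / (2 sigma1^2)); symmetric with unit
    diagonal and entries in (0, 1].
    """
    if sigma1 <= 0:
        raise ValueError(f"sigma1 must be positive, got {sigma1}")
    X = feats.features if isinstance(feats, PairFeatureMatrix) else np.asarray(feats)
    if not np.isfinite(X).all():
        raise ValueError("feature matrix contains non-finite values")
    if X.shape[0] == 1:
        return np.ones((1, 1))
    sq = squareform(pdist(X, metric="sqeuclidean"))
    W = np.exp(-sq / (2.0 * sigma1**2))
    np.fill_diagonal(W, 1.0)
    return W


def graph_laplacian(W: np.ndarray, normalized: bool = False) -> np.ndarray:
    """Graph Laplacian L = D - W, optionally normalized D^(-1/2) L D^(-1/2).

    Degrees are the row sums of W. With strictly positive similarities
    (squared-exponential W) degrees are strictly positive; they are floored
    at a tiny constant before inversion as an underflow guard.
    """
    W = np.asarray(W, dtype=float)
    if not np.allclose(W, W.T, atol=1e-10):
        raise ValueError("similarity matrix is not symmetric")
    deg = W.sum(axis=1)
    L = np.diag(deg) - W
    if not normalized:
        return L
    inv_sqrt = 1.0 / np.sqrt(np.maximum(deg, _DEGREE_FLOOR))
    return inv_sqrt[:, None] * L * inv_sqrt[None, :]


def kernel_matrix(
    feats: PairFeatureMatrix | np.ndarray,
    sigma2: float,
    m_labelled: int = 0,
) -> KernelMatrix:
    """Squared-exponential Mercer kernel over all feature rows.

    Same functional form as the similarity matrix; with sigma2 defaulted to
    sigma1 the two matrices coincide. Positive semi-definite up to numerical
    tolerance.
    """
    if sigma2 <= 0:
        raise ValueError(f"sigma2 must be positive, got {sigma2}")
    K = similarity_matrix(feats, sigma2)
    return KernelMatrix(K, m_labelled)


def build_manifold_graph(
    feats: PairFeatureMatrix,
    sigma1: Optional[float] = None,
    sigma2: Optional[float] = None,
    k_neighbors: int = 50,
    subsample_size: int = 1000,
    seed: int = 0,
) -> ManifoldGraph:
    """Estimate scales (when not given) and assemble W, D, L and L_norm."""
    if sigma1 is None:
        sigma1 = estimate_length_scale(feats, k_neighbors, subsample_size, seed)
    if sigma2 is None:
        sigma2 = sigma1
    W = similarity_matrix(feats, sigma1)
    deg = W.sum(axis=1)
    L = graph_laplacian(W, normalized=False)
    L_norm = graph_laplacian(W, normalized=True)
    return ManifoldGraph(W=W, degrees=deg, L=L, L_norm=L_norm,
                         sigma1=float(sigma1), sigma2=float(sigma2))
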