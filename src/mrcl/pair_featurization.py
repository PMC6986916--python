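"""Bivariate-histogram featurization of variable pairs.

Each ordered pair (i, j) of variables is represented by the scatter plot of
its n joint observations, summarised as a bivariate histogram on a fixed
regular grid over a truncation box (default [-3, 3]^2 on the standardized
scale). The vectorized bin counts are the feature vector of the pair; the
Euclidean distance between two such vectors is, up to a constant factor
shared by all pairs at common n, the L2 distance between the corresponding
histogram density estimates. A PCA step optionally reduces the M^2 raw
features to a lower dimension while (when no components are dropped)
preserving pairwise Euclidean distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .indexing import PairIndexer

DEFAULT_BOUNDS: tuple[float, float] = (-3.0, 3.0)
DEFAULT_BIN_WIDTH: float = 0.2


@dataclass
class DataMatrix:
    """Numeric data matrix: n samples (rows) by p named variables (columns)."""

    values: np.ndarray
    variable_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array (samples x variables)")
        n, p = self.values.shape
        if p != len(self.variable_names):
            raise ValueError(
                f"{len(self.variable_names)} variable names for {p} columns"
            )
        if p < 2:
            raise ValueError(f"need at least 2 variables, got p={p}")
        if n < 2:
            raise ValueError(f"need at least 2 samples, got n={n}")
        bad = np.argwhere(~np.isfinite(self.values))
        if bad.size:
            r, c = bad[0]
            raise ValueError(
                f"missing/non-finite value at sample {r}, "
                f"variable {self.variable_names[c]!r}"
            )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.variable_names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.variable_names)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DataMatrix":
        return cls(df.to_numpy(dtype=float), [str(c) for c in df.columns])


def read_data_matrix(path: str | Path, sep: Optional[str] = None) -> DataMatrix:
    """Read a delimited text data matrix (header row = variable names).

    The delimiter is inferred from the extension (.tsv -> tab, otherwise
    comma) unless given explicitly.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    return DataMatrix.from_frame(pd.read_csv(path, sep=sep))


@dataclass
class ScatterPlot:
    """The n joint observations of one ordered variable pair."""

    points: np.ndarray  # (n, 2); column 0 = source variable, column 1 = target
    bounds: tuple[float, float] = DEFAULT_BOUNDS

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must have shape (n, 2)")

    @property
    def n(self) -> int:
        return self.points.shape[0]

    def transpose(self) -> "ScatterPlot":
        """Scatter plot of the reversed pair (coordinates swapped)."""
        return ScatterPlot(self.points[:, ::-1].copy(), self.bounds)


@dataclass
class HistogramDensity:
    """Bivariate histogram on a regular M x M grid over a bounding box.

    ``counts[m1, m2]`` is the number of points in bin (m1, m2), where m1
    indexes the first (source) coordinate. The associated density estimate
    is piecewise constant with value counts/(n*h**2) on each bin; it
    integrates to one over the box.
    """

    counts: np.ndarray
    M: int
    h: float
    bounds: tuple[float, float] = DEFAULT_BOUNDS

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (self.M, self.M):
            raise ValueError("counts must be an M x M grid")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def density(self) -> np.ndarray:
        """Piecewise-constant density values on the grid."""
        return self.counts / (self.n * self.h**2)

    def vector(self) -> np.ndarray:
        """Row-major vectorization of the count grid (length M**2)."""
        return self.counts.ravel(order="C")


@dataclass
class PairFeatureMatrix:
    """m x d feature table, one row per ordered pair.

    ``stage`` is ``"raw-counts"`` (d = M**2 integer bin counts, each row
    summing to the common sample size n) or ``"pca"`` after dimension
    reduction. For the PCA stage the centering vector and loading matrix are
    retained so the projection is reproducible.
    """

    features: np.ndarray
    pair_index: PairIndexer
    stage: str = "raw-counts"
    pca_mean: Optional[np.ndarray] = None
    pca_components: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.shape[0] != self.pair_index.m:
            raise ValueError(
                f"{self.features.shape[0]} feature rows for "
                f"{self.pair_index.m} indexed pairs"
            )

    @property
    def m(self) -> int:
        return self.features.shape[0]

    @property
    def d(self) -> int:
        return self.features.shape[1]


def standardize_truncate(
    data: DataMatrix, bounds: tuple[float, float] = DEFAULT_BOUNDS
) -> DataMatrix:
    """Z-score each column by its own mean and sample s.d., then clip to bounds.

    Truncation is winsorizing (values are clipped, not removed) so every
    column keeps all n samples and every pair's histogram has a common total
    count. Raises if any column has zero variance.
    """
    lo, hi = bounds
    if not lo < hi:
        raise ValueError(f"invalid bounds {bounds}")
    mean = data.values.mean(axis=0)
    sd = data.values.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError(
            f"variable {data.variable_names[zero[0]]!r} has zero variance; "
            "cannot standardize"
        )
    z = (data.values - mean) / sd
    return DataMatrix(np.clip(z, lo, hi), list(data.variable_names))


def extract_scatter(data: DataMatrix, i: int, j: int,
                    bounds: tuple[float, float] = DEFAULT_BOUNDS) -> ScatterPlot:
    """Ordered scatter plot of pair (i, j): points (z_i^(l), z_j^(l)).

    Ordered-pair semantics: extract_scatter(data, j, i) is the coordinate
    transpose of extract_scatter(data, i, j).
    """
    p = data.p
    for idx in (i, j):
        if not 0 <= idx < p:
            raise IndexError(f"variable index {idx} out of range for p={p}")
    return ScatterPlot(data.values[:, [i, j]].copy(), bounds)


def histogram_density(s: ScatterPlot, M: int) -> HistogramDensity:
    """Bin a scatter plot on the regular M x M grid over its bounds.

    Bins are half-open [a, b) except the last along each axis, which is
    closed, so points exactly at the upper bound are counted. Points outside
    the bounds are an error: truncation must happen first.
    """
    if M < 1:
        raise ValueError(f"M must be >= 1, got {M}")
    lo, hi = s.bounds
    if s.n and (s.points.min() < lo or s.points.max() > hi):
        raise ValueError("scatter contains points outside bounds; truncate first")
    edges = np.linspace(lo, hi, M + 1)
    counts, _, _ = np.histogram2d(s.points[:, 0], s.points[:, 1],
                                  bins=(edges, edges))
    h = (hi - lo) / M
    return HistogramDensity(counts.astype(np.int64), M=M, h=h, bounds=s.bounds)


def density_l2_distance(a: HistogramDensity, b: HistogramDensity) -> float:
    """L2(Lebesgue) distance between two histogram density estimates.

    Both histograms must share the same grid. This is the sample analogue of
    the L2 distance between the underlying bivariate densities; when the two
    histograms have a common n it is proportional to the Euclidean distance
    between their count vectors (factor 1/(n*h)).
    """
    if a.M != b.M or a.bounds != b.bounds:
        raise ValueError("histograms are on different grids")
    diff = a.density() - b.density()
    return float(np.sqrt(np.sum(diff**2)) * a.h)


def bins_for_width(bounds: tuple[float, float], bin_width: float) -> int:
    """Number of bins per axis for a target bin width (e.g. 0.2 -> M = 30)."""
    lo, hi = bounds
    M = (hi - lo) / bin_width
    M_int = int(round(M))
    if not np.isclose(M, M_int):
        raise ValueError(
            f"bin width {bin_width} does not evenly divide bounds {bounds}"
        )
    return M_int


def featurize_pairs(
    data: DataMatrix,
    pairs: PairIndexer,
    M: Optional[int] = None,
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
) -> PairFeatureMatrix:
    """Histogram-featurize every indexed pair of a standardized data matrix.

    Row k of the result is the row-major vectorized M x M count grid of pair
    (i[k], j[k]). M defaults to the grid implied by bin width 0.2.
    """
    if M is None:
        M = bins_for_width(bounds, DEFAULT_BIN_WIDTH)
    lo, hi = bounds
    if data.values.min() < lo or data.values.max() > hi:
        raise ValueError("data contains values outside bounds; truncate first")
    edges = np.linspace(lo, hi, M + 1)
    # bin index per column, once; same edge convention as np.histogram2d
    # (half-open bins, closed last bin).
    idx = np.searchsorted(edges, data.values, side="right") - 1
    idx = np.clip(idx, 0, M - 1)
    feats = np.empty((pairs.m, M * M), dtype=float)
    for k, (i, j) in enumerate(pairs):
        flat = idx[:, i] * M + idx[:, j]
        feats[k] = np.bincount(flat, minlength=M * M)
    return PairFeatureMatrix(feats, pairs, stage="raw-counts")


def reduce_dimension(feats: PairFeatureMatrix, target_dim: int = 100) -> PairFeatureMatrix:
    """Project raw count features onto their top principal components.

    The PCA is fitted jointly on all m rows (labelled and unlabelled alike,
    matching the transductive setting), columns are mean-centered, and each
    component's sign is fixed by making its largest-magnitude loading
    positive. The number of retained components is min(target_dim, m, d);
    when nothing is discarded, pairwise Euclidean distances are preserved.
    """
    if target_dim < 1:
        raise ValueError(f"target_dim must be >= 1, got {target_dim}")
    if feats.stage != "raw-counts":
        raise ValueError("reduce_dimension expects raw-count features")
    n_comp = min(target_dim, feats.m, feats.d)
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(feats.features)
    components = pca.components_.copy()
    for c in range(n_comp):
        lead = np.argmax(np.abs(components[c]))
        if components[c, lead] < 0:
            components[c] *= -1.0
            scores[:, c] *= -1.0
    return PairFeatureMatrix(
        scores,
        feats.pair_index,
        stage="pca",
        pca_mean=pca.mean_.copy(),
        pca_components=components,
    )


def write_features(
    feats: PairFeatureMatrix,
    variable_names: Sequence[str],
    path: str | Path,
    sep: str = "\t",
) -> None:
    """Write a feature matrix as delimited text with source/target columns."""
    src = [variable_names[i] for i, _ in feats.pair_index]
    tgt = [variable_names[j] for _, j in feats.pair_index]
    df = pd.DataFrame(feats.features)
    df.columns = [f"f{c}" for c in range(feats.d)]
    df.insert(0, "target", tgt)
    df.insert(0, "source", src)
    df.to_csv(path, sep=sep, index=False)
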