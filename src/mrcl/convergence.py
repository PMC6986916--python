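"""Empirical convergence studies for the histogram density estimator.

Two finite-sample checks back the use of the bivariate histogram as the
featurization's density estimator:

* the L2 estimation error, with the rate-optimal bandwidth h ~ n^(-1/4),
  decays like n^(-1/4) — measured as the log-log slope of mean error
  against n;
* the sample distance between the histogram estimates of two fixed smooth
  densities converges to the true L2 distance between those densities as
  n grows (with the same shrinking bandwidth, which keeps the estimator
  consistent).

Ground-truth quantities come from the closed forms in :mod:`mrcl.density`,
so no numerical-quadrature error enters the comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .density import TruncatedGaussianMixture2D, histogram_l2_error
from .pair_featurization import (
    DEFAULT_BOUNDS,
    ScatterPlot,
    density_l2_distance,
    histogram_density,
)

# Moderately peaked three-component reference density; smooth on the box and
# far enough from uniform that the bias term of the histogram is exercised.
_REFERENCE_PARAMS = dict(
    weights=[0.45, 0.35, 0.2],
    means=[[-1.0, -0.8], [1.2, 0.6], [0.0, 1.4]],
    sds=[[0.9, 1.1], [0.8, 0.9], [1.2, 0.7]],
)

_ALT_PARAMS = dict(
    weights=[0.6, 0.4],
    means=[[0.8, -1.0], [-1.2, 1.2]],
    sds=[[1.0, 0.8], [0.9, 1.2]],
)


def reference_density(bounds=DEFAULT_BOUNDS) -> TruncatedGaussianMixture2D:
    return TruncatedGaussianMixture2D(bounds=bounds, **{
        k: np.asarray(v) for k, v in _REFERENCE_PARAMS.items()
    })


def alternative_density(bounds=DEFAULT_BOUNDS) -> TruncatedGaussianMixture2D:
    return TruncatedGaussianMixture2D(bounds=bounds, **{
        k: np.asarray(v) for k, v in _ALT_PARAMS.items()
    })


def optimal_bins(n: int, bounds=DEFAULT_BOUNDS) -> int:
    """Grid size implied by the rate-optimal bandwidth h = n^(-1/4)."""
    lo, hi = bounds
    return max(int(round((hi - lo) * n**0.25)), 1)


@dataclass
class RateStudy:
    """Result of the L2-error rate experiment."""

    n_values: np.ndarray
    mean_errors: np.ndarray
    slope: float  # fitted log-log exponent of mean error vs n
    intercept: float


def estimate_rate_exponent(
    n_values=None,
    replicates: int = 20,
    seed: int = 0,
    density: TruncatedGaussianMixture2D | None = None,
) -> RateStudy:
    """Measure the decay exponent of the histogram's mean L2 error.

    For each sample size n, draws ``replicates`` i.i.d. samples from the
    reference density, bins them with the rate-optimal bandwidth
    h = n^(-1/4), computes the exact L2 error of each histogram estimate,
    and fits a straight line to log(mean error) against log(n).
    """
    if n_values is None:
        n_values = 2 ** np.arange(8, 17)
    n_values = np.asarray(n_values, dtype=int)
    if density is None:
        density = reference_density()
    rng = np.random.default_rng(seed)
    mean_errors = np.empty(len(n_values))
    for a, n in enumerate(n_values):
        M = optimal_bins(int(n), density.bounds)
        errs = np.empty(replicates)
        for r in range(replicates):
            pts = density.sample(int(n), rng)
            hist = histogram_density(ScatterPlot(pts, density.bounds), M)
            errs[r] = histogram_l2_error(hist, density)
        mean_errors[a] = errs.mean()
    slope, intercept = np.polyfit(np.log(n_values), np.log(mean_errors), 1)
    return RateStudy(n_values, mean_errors, float(slope), float(intercept))


@dataclass
class ConsistencyStudy:
    """Result of the sample-distance consistency experiment."""

    n_values: np.ndarray
    true_distance: float
    median_abs_errors: np.ndarray  # per n: median |d_sample - d_true|


def distance_consistency_curve(
    n_values=(100, 1_000, 10_000),
    replicates: int = 20,
    seed: int = 0,
) -> ConsistencyStudy:
    """Convergence of the sample histogram distance to the true L2 distance.

    Two fixed smooth densities are sampled at each n; the L2 distance
    between their histogram estimates (bandwidth h = n^(-1/4)) is compared
    against the closed-form L2 distance between the true densities, and the
    median absolute error over replicates is recorded per n.
    """
    pi1 = reference_density()
    pi2 = alternative_density()
    d_true = pi1.l2_distance(pi2)
    rng = np.random.default_rng(seed)
    n_values = np.asarray(n_values, dtype=int)
    med_errs = np.empty(len(n_values))
    for a, n in enumerate(n_values):
        M = optimal_bins(int(n))
        errs = np.empty(replicates)
        for r in range(replicates):
            h1 = histogram_density(
                ScatterPlot(pi1.sample(int(n), rng), pi1.bounds), M)
            h2 = histogram_density(
                ScatterPlot(pi2.sample(int(n), rng), pi2.bounds), M)
            errs[r] = abs(density_l2_distance(h1, h2) - d_true)
        med_errs[a] = np.median(errs)
    return ConsistencyStudy(n_values, float(d_true), med_errs)
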