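"""Smooth reference densities on the truncation box.

Axis-aligned Gaussian mixtures truncated to the bounding box serve as
ground-truth bivariate densities for validating the histogram estimator:
their bin probabilities, squared L2 norms and cross inner products are all
available in closed form (1-D Gaussian CDFs and Gaussian product integrals),
so the L2 estimation error of a histogram and the L2 distance between two
densities can be computed without Monte-Carlo quadrature error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .pair_featurization import DEFAULT_BOUNDS, HistogramDensity


def _gauss_pair_integral(mu1, s1, mu2, s2, a, b):
    """Integral of N(z; mu1, s1^2) * N(z; mu2, s2^2) over [a, b]."""
    var_sum = s1**2 + s2**2
    prefac = stats.norm.pdf(mu1 - mu2, scale=np.sqrt(var_sum))
    var_bar = (s1**2 * s2**2) / var_sum
    mu_bar = (mu1 * s2**2 + mu2 * s1**2) / var_sum
    s_bar = np.sqrt(var_bar)
    mass = stats.norm.cdf(b, mu_bar, s_bar) - stats.norm.cdf(a, mu_bar, s_bar)
    return prefac * mass


@dataclass
class TruncatedGaussianMixture2D:
    """Mixture of axis-aligned bivariate Gaussians truncated to a box.

    Each component g has weight w_g, means (mx_g, my_g) and standard
    deviations (sx_g, sy_g); the component densities are renormalized to
    integrate to one over the box, so the mixture is a proper density there.
    Twice continuously differentiable on the open box.
    """

    weights: np.ndarray
    means: np.ndarray  # (G, 2)
    sds: np.ndarray  # (G, 2)
    bounds: tuple[float, float] = DEFAULT_BOUNDS

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("mixture weights must sum to 1")
        a, b = self.bounds
        # per-component box mass along each axis, for renormalization
        self._axis_mass = stats.norm.cdf(
            b, self.means, self.sds
        ) - stats.norm.cdf(a, self.means, self.sds)
        self._box_mass = self._axis_mass.prod(axis=1)

    @property
    def G(self) -> int:
        return len(self.weights)

    def pdf(self, z1, z2):
        z1 = np.asarray(z1, dtype=float)
        z2 = np.asarray(z2, dtype=float)
        out = np.zeros(np.broadcast(z1, z2).shape)
        for g in range(self.G):
            out += (
                self.weights[g]
                / self._box_mass[g]
                * stats.norm.pdf(z1, self.means[g, 0], self.sds[g, 0])
                * stats.norm.pdf(z2, self.means[g, 1], self.sds[g, 1])
            )
        return out

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n i.i.d. points inside the box (component-wise rejection)."""
        a, b = self.bounds
        comp = rng.choice(self.G, size=n, p=self.weights)
        pts = np.empty((n, 2))
        todo = np.arange(n)
        while todo.size:
            draw = rng.normal(self.means[comp[todo]], self.sds[comp[todo]])
            pts[todo] = draw
            inside = ((draw >= a) & (draw <= b)).all(axis=1)
            todo = todo[~inside]
        return pts

    def bin_probabilities(self, M: int) -> np.ndarray:
        """Exact probability mass of each bin of the regular M x M grid."""
        a, b = self.bounds
        edges = np.linspace(a, b, M + 1)
        P = np.zeros((M, M))
        for g in range(self.G):
            cdf_x = stats.norm.cdf(edges, self.means[g, 0], self.sds[g, 0])
            cdf_y = stats.norm.cdf(edges, self.means[g, 1], self.sds[g, 1])
            px = np.diff(cdf_x)
            py = np.diff(cdf_y)
            P += self.weights[g] / self._box_mass[g] * np.outer(px, py)
        return P

    def l2_inner(self, other: "TruncatedGaussianMixture2D") -> float:
        """Closed-form inner product  integral(pi * pi~)  over the box."""
        if self.bounds != other.bounds:
            raise ValueError("densities live on different boxes")
        a, b = self.bounds
        total = 0.0
        for g in range(self.G):
            for g2 in range(other.G):
                ix = _gauss_pair_integral(
                    self.means[g, 0], self.sds[g, 0],
                    other.means[g2, 0], other.sds[g2, 0], a, b,
                )
                iy = _gauss_pair_integral(
                    self.means[g, 1], self.sds[g, 1],
                    other.means[g2, 1], other.sds[g2, 1], a, b,
                )
                total += (
                    self.weights[g] * other.weights[g2]
                    / (self._box_mass[g] * other._box_mass[g2])
                    * ix * iy
                )
        return float(total)

    def l2_norm_sq(self) -> float:
        return self.l2_inner(self)

    def l2_distance(self, other: "TruncatedGaussianMixture2D") -> float:
        """L2(Lebesgue) distance between the two true densities."""
        d2 = self.l2_norm_sq() - 2.0 * self.l2_inner(other) + other.l2_norm_sq()
        return float(np.sqrt(max(d2, 0.0)))


def histogram_l2_error(hist: HistogramDensity,
                       density: TruncatedGaussianMixture2D) -> float:
    """Exact L2 error between a histogram estimate and the true density.

    With the histogram piecewise constant at kappa_B = x_B/(n h^2) on bin B,
        error^2 = int pi^2 - 2 sum_B kappa_B P_B + h^2 sum_B kappa_B^2,
    where P_B is the true bin mass; all terms are closed-form.
    """
    if hist.bounds != density.bounds:
        raise ValueError("histogram and density are on different boxes")
    kappa = hist.density()
    P = density.bin_probabilities(hist.M)
    err2 = (
        density.l2_norm_sq()
        - 2.0 * float(np.sum(kappa * P))
        + hist.h**2 * float(np.sum(kappa**2))
    )
    return float(np.sqrt(max(err2, 0.0)))
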