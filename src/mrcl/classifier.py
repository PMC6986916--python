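"""Laplacian-regularized least-squares transduction.

Scores for unlabelled pairs minimize, over functions f in the RKHS of the
kernel K,

    (1/m_L) ||y^L - f^L||^2  +  (lambda1/m^2) f' L f  +  lambda2 ||f||_HK^2,

a squared-error fit to the known labels plus a manifold-smoothness penalty
(graph Laplacian L, normalized by default) and an RKHS-norm penalty that
keeps the minimizer well-defined. By the representer theorem f = K alpha
and the minimizer has the closed form

    alpha_hat = (J K + lambda2 m_L I + (lambda1 m_L / m^2) L K)^(-1) [y^L; 0]

with J the diagonal selector of labelled entries; the score vector is
f_hat = K alpha_hat and predicted labels are sign(f_hat) on the unlabelled
block. Pairs must be ordered labelled-first throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import get_lapack_funcs, lu_factor, lu_solve

from .manifold_graph import KernelMatrix

_RESIDUAL_TOL = 1e-8


@dataclass
class LapRLSConfig:
    """Penalty weights for the transductive least-squares objective.

    lambda1 weighs the Laplacian smoothness term and may be zero (ridge
    limit); lambda2 weighs the RKHS norm and must be positive so the
    minimizer is unique. Both default to the small value 0.001, to which
    results are broadly insensitive.
    """

    lambda1: float = 0.001
    lambda2: float = 0.001
    use_normalized_laplacian: bool = True

    def __post_init__(self) -> None:
        if self.lambda1 < 0:
            raise ValueError("lambda1 must be non-negative")
        if self.lambda2 <= 0:
            raise ValueError("lambda2 must be positive")


@dataclass
class ClassifierFit:
    """Fitted transduction: scores at all m pairs plus solver diagnostics."""

    f_hat: np.ndarray
    m_labelled: int
    y_train: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    @property
    def f_labelled(self) -> np.ndarray:
        """In-sample scores at labelled pairs (diagnostics only)."""
        return self.f_hat[: self.m_labelled]

    @property
    def f_unlabelled(self) -> np.ndarray:
        return self.f_hat[self.m_labelled:]


def _check_labels(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if y.ndim != 1:
        raise ValueError("labels must be a 1-D vector")
    if not np.all(np.isin(y, (-1.0, 1.0))):
        raise ValueError("labels must take values in {-1, +1}")
    return y


def fit_transduce(
    kernel: KernelMatrix,
    laplacian: np.ndarray,
    y_labels: np.ndarray,
    config: LapRLSConfig | None = None,
) -> ClassifierFit:
    """Solve the transductive objective in closed form.

    The linear system (J K + lambda2 m_L I + (lambda1 m_L/m^2) L K) alpha =
    [y^L; 0] is generally non-symmetric and is solved by dense LU with a
    residual check; an ill-conditioned system beyond the residual tolerance
    raises, reporting a reciprocal-condition estimate.
    """
    if config is None:
        config = LapRLSConfig()
    y = _check_labels(y_labels)
    m = kernel.m
    m_L = len(y)
    if m_L != kernel.m_labelled:
        raise ValueError(
            f"{m_L} labels but kernel partition has {kernel.m_labelled} "
            "labelled rows"
        )
    if m_L < 1:
        raise ValueError("at least one labelled pair is required")
    laplacian = np.asarray(laplacian, dtype=float)
    if laplacian.shape != (m, m):
        raise ValueError("laplacian must be m x m")

    K = kernel.K_full
    JK = np.zeros_like(K)
    JK[:m_L] = K[:m_L]  # J K: unlabelled rows zeroed
    A = JK + config.lambda2 * m_L * np.eye(m)
    if config.lambda1 != 0.0:
        A += (config.lambda1 * m_L / m**2) * (laplacian @ K)
    b = np.concatenate([y, np.zeros(m - m_L)])

    lu, piv = lu_factor(A)
    alpha = lu_solve((lu, piv), b)
    residual = float(np.linalg.norm(A @ alpha - b) / np.linalg.norm(b))
    gecon = get_lapack_funcs("gecon", (A,))
    rcond, _ = gecon(lu, np.linalg.norm(A, 1))
    if not np.isfinite(alpha).all() or residual > _RESIDUAL_TOL:
        raise np.linalg.LinAlgError(
            f"transduction system is ill-conditioned (relative residual "
            f"{residual:.2e}, reciprocal condition estimate {rcond:.2e})"
        )
    f_hat = K @ alpha
    return ClassifierFit(
        f_hat=f_hat,
        m_labelled=m_L,
        y_train=y.copy(),
        diagnostics={
            "residual": residual,
            "condition_estimate": float(1.0 / rcond) if rcond > 0 else np.inf,
            "alpha": alpha,
        },
    )


def laprls_objective(
    alpha: np.ndarray,
    kernel: KernelMatrix,
    laplacian: np.ndarray,
    y_labels: np.ndarray,
    config: LapRLSConfig | None = None,
) -> float:
    """Representer-form objective value at coefficients alpha.

    (1/m_L)||y^L - (K alpha)^L||^2 + (lambda1/m^2)(K alpha)' L (K alpha)
    + lambda2 alpha' K alpha. Used for diagnostics and as a test oracle.
    """
    if config is None:
        config = LapRLSConfig()
    y = _check_labels(y_labels)
    alpha = np.asarray(alpha, dtype=float)
    m = kernel.m
    m_L = len(y)
    if alpha.shape != (m,):
        raise ValueError(f"alpha must have length m={m}")
    f = kernel.K_full @ alpha
    fit = np.sum((y - f[:m_L]) ** 2) / m_L
    smooth = config.lambda1 / m**2 * float(f @ laplacian @ f)
    norm = config.lambda2 * float(alpha @ kernel.K_full @ alpha)
    return fit + smooth + norm


def classify(fit: ClassifierFit) -> np.ndarray:
    """Sign labels for the unlabelled pairs: +1 iff the score is positive.

    A score of exactly zero is labelled -1 (conservative: no edge). The raw
    real-valued scores remain available on the fit for ranking.
    """
    return np.where(fit.f_unlabelled > 0, 1, -1).astype(int)
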