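"""Gold standards, label-sampling designs, ROC/AUC scoring and baselines.

An interventional gold standard declares "i causes j" when the robust
z-score zeta_ij = |Z_ij^int - median_j| / IQR_j exceeds a threshold tau,
with the median and inter-quartile range computed from a random half of
the observational samples (the other half is reserved as training data so
the learner never sees what built the ground truth). Labels for training
are revealed either uniformly at random over pairs or row-wise (all
outgoing effects of selected source variables), and performance is always
measured on the unlabelled pairs only. Pearson/Kendall correlation and a
k-nearest-neighbour vote on the histogram features serve as baselines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.metrics import roc_auc_score, roc_curve

from .indexing import PairIndexer, build_pair_index
from .learner import ANCESTRAL, PartialLabels
from .pair_featurization import DataMatrix, PairFeatureMatrix


@dataclass
class GoldStandard:
    """Interventional ground truth from robust z-scores."""

    zeta: np.ndarray  # p x p, zeta[i, j] = effect of intervening on i, seen at j
    adjacency: np.ndarray  # binary, zeta > tau (strict)
    tau: float
    obs_split_seed: int
    training_data: DataMatrix  # observational half not used for median/IQR
    obs_medians: np.ndarray = field(default=None)
    obs_iqrs: np.ndarray = field(default=None)
    variable_names: list[str] = field(default_factory=list)


def gold_standard(
    intervention_effects: np.ndarray | pd.DataFrame,
    observational: DataMatrix,
    tau: float = 5.0,
    seed: int = 0,
    include_diagonal: bool = False,
) -> GoldStandard:
    """Threshold robust z-scores of post-intervention change into edges.

    ``intervention_effects[i, j]`` is the single measured level of variable
    j after intervening on variable i (aggregation across replicates, if
    any, is the caller's choice). The observational samples are split in
    half at random (seeded): one half yields each variable's median and
    IQR, the other is returned as training data. An edge (i, j) is declared
    iff zeta_ij > tau, strictly; ties at tau are non-edges.
    """
    Z = np.asarray(
        intervention_effects.values
        if isinstance(intervention_effects, pd.DataFrame)
        else intervention_effects,
        dtype=float,
    )
    p = observational.p
    if Z.shape != (p, p):
        raise ValueError(f"intervention effects must be {p} x {p}")
    n = observational.n
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_stats = n // 2
    if n_stats < 4:
        raise ValueError("need at least 4 observational samples in the "
                         "median/IQR half")
    stats_half = observational.values[order[:n_stats]]
    train_half = observational.values[order[n_stats:]]

    med = np.median(stats_half, axis=0)
    q75, q25 = np.percentile(stats_half, [75, 25], axis=0, method="linear")
    iqr = q75 - q25
    zero = np.flatnonzero(iqr == 0)
    if zero.size:
        raise ValueError(
            f"variable {observational.variable_names[zero[0]]!r} has zero "
            "observational IQR; robust z-score undefined"
        )
    zeta = np.abs(Z - med[None, :]) / iqr[None, :]
    adjacency = (zeta > tau).astype(int)
    if not include_diagonal:
        np.fill_diagonal(adjacency, 0)
    return GoldStandard(
        zeta=zeta,
        adjacency=adjacency,
        tau=tau,
        obs_split_seed=seed,
        training_data=DataMatrix(train_half, list(observational.variable_names)),
        obs_medians=med,
        obs_iqrs=iqr,
        variable_names=list(observational.variable_names),
    )


def _labels_from_adjacency(adjacency: np.ndarray, idx, pairs: PairIndexer,
                           design: str) -> PartialLabels:
    y = np.array(
        [1 if adjacency[pairs.pair_of(k)] else -1 for k in idx], dtype=int
    )
    labels = PartialLabels(pairs, np.asarray(idx, dtype=int), y,
                           semantics=ANCESTRAL)
    labels.design = design  # experiment bookkeeping
    return labels


def sample_labels_random(
    adjacency: np.ndarray,
    rho: float,
    seed: int = 0,
    include_diagonal: bool = False,
) -> PartialLabels:
    """Reveal floor(rho * m) uniformly sampled pair labels as training set."""
    adjacency = np.asarray(adjacency)
    p = adjacency.shape[0]
    if adjacency.shape != (p, p):
        raise ValueError("adjacency must be square")
    if not 0 < rho <= 1:
        raise ValueError("rho must lie in (0, 1]")
    pairs = build_pair_index(p, include_diagonal=include_diagonal)
    m_L = int(np.floor(rho * pairs.m))
    if m_L == 0:
        raise ValueError(f"rho={rho} reveals zero labels (m={pairs.m})")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(pairs.m, size=m_L, replace=False))
    return _labels_from_adjacency(adjacency, idx, pairs, design="random")


def sample_labels_rowwise(
    adjacency: np.ndarray,
    rho: float,
    seed: int = 0,
    include_diagonal: bool = False,
) -> PartialLabels:
    """Reveal all outgoing labels of floor(rho * p) sampled source variables.

    Every pair whose source was sampled is labelled; pairs from unsampled
    sources form the unlabelled set, so evaluation concerns interventions
    on entirely unseen sources.
    """
    adjacency = np.asarray(adjacency)
    p = adjacency.shape[0]
    if adjacency.shape != (p, p):
        raise ValueError("adjacency must be square")
    if not 0 < rho <= 1:
        raise ValueError("rho must lie in (0, 1]")
    n_rows = int(np.floor(rho * p))
    if n_rows == 0:
        raise ValueError(f"rho={rho} samples zero source rows (p={p})")
    pairs = build_pair_index(p, include_diagonal=include_diagonal)
    rng = np.random.default_rng(seed)
    sources = set(rng.choice(p, size=n_rows, replace=False).tolist())
    idx = np.array([k for k, (i, _) in enumerate(pairs) if i in sources],
                   dtype=int)
    return _labels_from_adjacency(adjacency, idx, pairs, design="rowwise")


@dataclass
class EvalResult:
    """ROC curve and its area for one test set."""

    auc: float
    roc: np.ndarray  # (n_thresholds, 2) columns fpr, tpr
    test_set: Optional[np.ndarray] = None
    design: Optional[str] = None
    rho: Optional[float] = None


def roc_auc(
    scores: np.ndarray,
    truth: np.ndarray,
    absolute: bool = False,
    **meta,
) -> EvalResult:
    """ROC curve and AUC of real-valued scores against binary truth.

    The AUC is the midrank Mann-Whitney statistic, identical to the
    trapezoidal area under the ROC curve. ``absolute`` ranks by |score|,
    appropriate for signed symmetric baselines such as correlations; the
    transductive scores are ranked raw.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth)
    truth = (truth > 0).astype(int)
    if truth.min() == truth.max():
        raise ValueError("truth contains a single class; ROC undefined")
    s = np.abs(scores) if absolute else scores
    fpr, tpr, _ = roc_curve(truth, s)
    return EvalResult(
        auc=float(roc_auc_score(truth, s)),
        roc=np.column_stack([fpr, tpr]),
        **meta,
    )


def baseline_correlation(
    data: DataMatrix,
    method: str = "pearson",
    pairs: Optional[PairIndexer] = None,
) -> np.ndarray:
    """Correlation-coefficient scores for all ordered pairs.

    Correlation is symmetric, so both orderings of a pair receive the same
    score; absolute values are taken at evaluation time. Returns the p x p
    correlation matrix, or a vector aligned with ``pairs`` when given.
    """
    if method not in ("pearson", "kendall"):
        raise ValueError(f"unknown correlation method {method!r}")
    if data.n < 3:
        raise ValueError("need at least 3 samples for correlation scores")
    sd = data.values.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError(
            f"variable {data.variable_names[zero[0]]!r} has zero variance"
        )
    corr = data.to_frame().corr(method=method).to_numpy()
    if pairs is None:
        return corr
    return np.array([corr[i, j] for i, j in pairs])


def baseline_knn(
    feats: PairFeatureMatrix,
    labels: PartialLabels,
    k: int,
) -> np.ndarray:
    """k-nearest-neighbour vote on pair features.

    The score of each unlabelled pair is the mean label of its k nearest
    labelled pairs in Euclidean feature space; distance ties break by pair
    index (stable sort). Returns scores aligned with
    ``labels.unlabelled_idx``.
    """
    if k < 1:
        raise ValueError("k must be positive")
    if k > labels.m_labelled:
        raise ValueError(
            f"k={k} exceeds the number of labelled pairs ({labels.m_labelled})"
        )
    X = feats.features
    L_idx = labels.labelled_idx
    U_idx = labels.unlabelled_idx
    d = cdist(X[U_idx], X[L_idx])
    order = np.argsort(d, axis=1, kind="stable")[:, :k]
    return labels.y[order].mean(axis=1)


def passes_sparsity_screen(adjacency: np.ndarray,
                           min_fraction: float = 0.025) -> bool:
    """Candidate-set screen: at least this fraction of pairs show an effect."""
    adjacency = np.asarray(adjacency)
    p = adjacency.shape[0]
    off = ~np.eye(p, dtype=bool)
    return adjacency[off].mean() >= min_fraction


def passes_rowwise_screen(adjacency: np.ndarray,
                          min_row_fraction: float = 0.5) -> bool:
    """Row-wise-design screen: enough rows have at least one effect."""
    adjacency = np.asarray(adjacency)
    A = adjacency.copy()
    np.fill_diagonal(A, 0)
    return (A.sum(axis=1) > 0).mean() >= min_row_fraction
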