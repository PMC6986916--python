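"""End-to-end estimator: data matrix + partial causal labels -> directed graph.

Ties the pipeline together: standardize/truncate the data, histogram-
featurize every ordered variable pair, PCA-reduce, build the similarity
graph and kernel, transduce labels from the known pairs to the unknown
ones, and assemble the estimated causal graph, whose edge set is exactly
the set of pairs with predicted (or known) label +1. The graph may contain
cycles; its semantics tag (ancestral vs direct) is inherited from the label
source and never altered by computation.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import networkx as nx
import numpy as np
import pandas as pd

from . import classifier as _clf
from . import manifold_graph as _mg
from . import pair_featurization as _pf
from .indexing import PairIndexer, build_pair_index

ANCESTRAL = "ancestral"
DIRECT = "direct"


@dataclass
class PartialLabels:
    """Known causal labels on a subset L of the indexed pairs.

    ``labelled_idx`` holds pair indices (into ``pair_index``) whose labels
    ``y`` in {-1, +1} are known; the complement is the unlabelled set U to
    be transduced. ``semantics`` records whether the labels describe
    ancestral (total) or direct causal relations.
    """

    pair_index: PairIndexer
    labelled_idx: np.ndarray
    y: np.ndarray
    semantics: str = ANCESTRAL

    def __post_init__(self) -> None:
        self.labelled_idx = np.asarray(self.labelled_idx, dtype=int)
        self.y = np.asarray(self.y, dtype=int)
        if self.labelled_idx.shape != self.y.shape:
            raise ValueError("labelled_idx and y must have equal length")
        if len(self.labelled_idx) < 1:
            raise ValueError("at least one labelled pair is required")
        if len(np.unique(self.labelled_idx)) != len(self.labelled_idx):
            raise ValueError("duplicate pair indices in labelled set")
        if self.labelled_idx.min() < 0 or self.labelled_idx.max() >= self.pair_index.m:
            raise ValueError("labelled pair index out of range")
        if not np.all(np.isin(self.y, (-1, 1))):
            raise ValueError("labels must take values in {-1, +1}")
        if self.semantics not in (ANCESTRAL, DIRECT):
            raise ValueError(f"unknown semantics {self.semantics!r}")

    @property
    def m_labelled(self) -> int:
        return len(self.labelled_idx)

    @property
    def unlabelled_idx(self) -> np.ndarray:
        mask = np.ones(self.pair_index.m, dtype=bool)
        mask[self.labelled_idx] = False
        return np.flatnonzero(mask)

    @property
    def m_unlabelled(self) -> int:
        return self.pair_index.m - self.m_labelled

    def test_indices(self, exclude_diagonal: bool = True) -> np.ndarray:
        """Unlabelled pair indices for evaluation (self-pairs dropped)."""
        idx = self.unlabelled_idx
        if exclude_diagonal and self.pair_index.include_diagonal:
            keep = [a for a, k in enumerate(idx)
                    if self.pair_index.pair_of(k)[0] != self.pair_index.pair_of(k)[1]]
            idx = idx[keep]
        return idx


def assemble_labels(
    edges: Iterable[tuple[str, str, int]] | pd.DataFrame,
    pairs: PairIndexer,
    variable_names: list[str],
    semantics: str = ANCESTRAL,
) -> PartialLabels:
    """Map a labelled edge list (source, target, label) onto pair indices.

    Edges reference variables by name; labels must be -1 or +1. Duplicate
    edges with conflicting labels raise; consistent duplicates collapse.
    When the pair index includes the diagonal, self-pairs without an
    explicit label are auto-labelled +1 (and therefore never enter the
    unlabelled/test partition).
    """
    if isinstance(edges, pd.DataFrame):
        edges = list(edges[["source", "target", "label"]].itertuples(index=False))
    name_to_idx = {name: i for i, name in enumerate(variable_names)}
    seen: dict[int, int] = {}
    for src, tgt, lab in edges:
        lab = int(lab)
        if lab not in (-1, 1):
            raise ValueError(f"label for edge ({src}, {tgt}) must be -1 or +1")
        try:
            i, j = name_to_idx[src], name_to_idx[tgt]
        except KeyError as e:
            raise KeyError(f"unknown variable name {e.args[0]!r} in edge list") from None
        k = pairs.k_of(i, j)
        if k in seen and seen[k] != lab:
            raise ValueError(
                f"conflicting duplicate labels for pair ({src}, {tgt})"
            )
        seen[k] = lab
    if pairs.include_diagonal:
        for i in range(pairs.p):
            k = pairs.k_of(i, i)
            seen.setdefault(k, 1)
    if not seen:
        raise ValueError("empty label set: the estimator is undefined without "
                         "background knowledge")
    idx = np.array(sorted(seen), dtype=int)
    y = np.array([seen[k] for k in idx], dtype=int)
    return PartialLabels(pairs, idx, y, semantics=semantics)


@dataclass
class MRCLConfig:
    """All tunable parameters of the pipeline, with field defaults."""

    bounds: tuple[float, float] = _pf.DEFAULT_BOUNDS
    bin_width: float = _pf.DEFAULT_BIN_WIDTH
    pca_dim: Optional[int] = 100
    include_diagonal: bool = False
    sigma1: Optional[float] = None  # None = estimate from data
    sigma2: Optional[float] = None  # None = set equal to sigma1
    knn_for_scale: int = 50
    scale_subsample: int = 1000
    lambda1: float = 0.001
    lambda2: float = 0.001
    use_normalized_laplacian: bool = True
    cache_dir: Optional[str] = None


@dataclass
class CausalGraph:
    """Estimated directed causal graph (cycles permitted, no self-loops

    unless the diagonal is indexed). An edge (i, j) is present exactly when
    the pair's label — known or predicted — is +1."""

    variable_names: list[str]
    edges: list[tuple[str, str]]
    edge_scores: dict[tuple[str, str], float]
    semantics: str

    def adjacency(self) -> np.ndarray:
        p = len(self.variable_names)
        idx = {name: i for i, name in enumerate(self.variable_names)}
        A = np.zeros((p, p), dtype=int)
        for s, t in self.edges:
            A[idx[s], idx[t]] = 1
        return A

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph(semantics=self.semantics)
        g.add_nodes_from(self.variable_names)
        for e in self.edges:
            g.add_edge(*e, score=self.edge_scores[e])
        return g


@dataclass
class MRCLResult:
    """Full output of one estimator run."""

    scores: pd.DataFrame  # source, target, score, predicted_label, labelled
    graph: CausalGraph
    fit: _clf.ClassifierFit
    manifold: _mg.ManifoldGraph
    labels: PartialLabels
    config: MRCLConfig
    # scores of unlabelled pairs, aligned with labels.unlabelled_idx
    unlabelled_scores: np.ndarray = field(default=None)


def _stage(name):
    """Decorator-free stage wrapper: re-raise with the stage name attached."""
    class _ctx:
        def __init__(self, label):
            self.label = label

        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, _StageError):
                raise _StageError(f"[stage {self.label}] {exc}") from exc
            return False

    return _ctx(name)


class _StageError(RuntimeError):
    pass


def _cached_featurize(data, pairs, M, bounds, cache_dir):
    if cache_dir is None:
        return _pf.featurize_pairs(data, pairs, M=M, bounds=bounds)
    key = hashlib.sha256()
    key.update(np.ascontiguousarray(data.values).tobytes())
    key.update(repr((M, bounds, pairs.p, pairs.include_diagonal)).encode())
    path = Path(cache_dir) / f"features-{key.hexdigest()[:16]}.npy"
    if path.exists():
        return _pf.PairFeatureMatrix(np.load(path), pairs, stage="raw-counts")
    feats = _pf.featurize_pairs(data, pairs, M=M, bounds=bounds)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.save(path, feats.features)
    return feats


def run_mrcl(
    data: _pf.DataMatrix,
    labels: PartialLabels,
    config: MRCLConfig | None = None,
    seed: int = 0,
) -> MRCLResult:
    """Run the full pipeline and assemble the estimated causal graph.

    Deterministic given data, labels, config and seed (the seed drives only
    the length-scale subsample). Stage failures are re-raised tagged with
    the stage name.
    """
    if config is None:
        config = MRCLConfig()
    pairs = labels.pair_index
    if pairs.p != data.p:
        raise ValueError(
            f"labels indexed over p={pairs.p} variables but data has p={data.p}"
        )

    with _stage("standardize_truncate"):
        std = _pf.standardize_truncate(data, config.bounds)
    with _stage("featurize_pairs"):
        M = _pf.bins_for_width(config.bounds, config.bin_width)
        feats = _cached_featurize(std, pairs, M, config.bounds, config.cache_dir)
    with _stage("reduce_dimension"):
        if config.pca_dim is not None:
            feats = _pf.reduce_dimension(feats, config.pca_dim)

    # order pairs labelled-first for the partitioned solve
    L_idx = labels.labelled_idx
    U_idx = labels.unlabelled_idx
    perm = np.concatenate([L_idx, U_idx])
    X = feats.features[perm]

    with _stage("length_scale"):
        sigma1 = config.sigma1
        if sigma1 is None:
            sigma1 = _mg.estimate_length_scale(
                X, config.knn_for_scale, config.scale_subsample, seed)
        sigma2 = config.sigma2 if config.sigma2 is not None else sigma1
    with _stage("manifold_graph"):
        W = _mg.similarity_matrix(X, sigma1)
        lap = _mg.graph_laplacian(W, normalized=config.use_normalized_laplacian)
        manifold = _mg.ManifoldGraph(
            W=W, degrees=W.sum(axis=1),
            L=_mg.graph_laplacian(W, normalized=False),
            L_norm=_mg.graph_laplacian(W, normalized=True),
            sigma1=float(sigma1), sigma2=float(sigma2),
        )
        kernel = _mg.kernel_matrix(X, sigma2, m_labelled=len(L_idx))
    with _stage("fit_transduce"):
        clf_config = _clf.LapRLSConfig(
            lambda1=config.lambda1, lambda2=config.lambda2,
            use_normalized_laplacian=config.use_normalized_laplacian,
        )
        fit = _clf.fit_transduce(kernel, lap, labels.y, clf_config)
        y_hat_U = _clf.classify(fit)

    # assemble per-pair table in original pair order
    names = data.variable_names
    score_all = np.empty(pairs.m)
    label_all = np.empty(pairs.m, dtype=int)
    is_labelled = np.zeros(pairs.m, dtype=bool)
    score_all[L_idx] = fit.f_labelled
    score_all[U_idx] = fit.f_unlabelled
    label_all[L_idx] = labels.y  # known labels stand as-is
    label_all[U_idx] = y_hat_U
    is_labelled[L_idx] = True

    rows = []
    edges = []
    edge_scores = {}
    for k, (i, j) in enumerate(pairs):
        rows.append((names[i], names[j], score_all[k], label_all[k],
                     bool(is_labelled[k])))
        if label_all[k] == 1:
            edges.append((names[i], names[j]))
            edge_scores[(names[i], names[j])] = float(score_all[k])
    scores = pd.DataFrame(
        rows, columns=["source", "target", "score", "predicted_label", "labelled"]
    )
    graph = CausalGraph(list(names), edges, edge_scores,
                        semantics=labels.semantics)
    return MRCLResult(
        scores=scores, graph=graph, fit=fit, manifold=manifold,
        labels=labels, config=config,
        unlabelled_scores=fit.f_unlabelled.copy(),
    )
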