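"""Linear indexing of ordered variable pairs.

Causal-edge learning treats every ordered pair (i, j) of variables as one
classification object. A :class:`PairIndexer` fixes a deterministic bijection
between linear indices k = 0..m-1 and ordered pairs, which all feature
matrices, similarity matrices and label vectors share.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class PairIndexer:
    """Bijection between linear pair indices and ordered variable pairs.

    Pairs are enumerated in row-major order: source index i is the outer
    loop, target index j the inner one. Self-pairs (i, i) are included only
    when ``include_diagonal`` is set, giving m = p**2 instead of p*(p-1).
    """

    p: int
    include_diagonal: bool = False
    pairs: tuple[tuple[int, int], ...] = field(init=False)
    _k_of: dict[tuple[int, int], int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.p < 2:
            raise ValueError(f"need at least 2 variables, got p={self.p}")
        pairs = tuple(
            (i, j)
            for i in range(self.p)
            for j in range(self.p)
            if self.include_diagonal or i != j
        )
        object.__setattr__(self, "pairs", pairs)
        object.__setattr__(self, "_k_of", {ij: k for k, ij in enumerate(pairs)})

    @property
    def m(self) -> int:
        """Total number of ordered pairs."""
        return len(self.pairs)

    def k_of(self, i: int, j: int) -> int:
        """Linear index of the ordered pair (i, j)."""
        try:
            return self._k_of[(i, j)]
        except KeyError:
            raise KeyError(f"pair ({i}, {j}) is not indexed") from None

    def pair_of(self, k: int) -> tuple[int, int]:
        """Ordered pair at linear index k."""
        return self.pairs[k]

    def __len__(self) -> int:
        return self.m

    def __iter__(self):
        return iter(self.pairs)


def build_pair_index(p: int, include_diagonal: bool = False) -> PairIndexer:
    """Enumerate all ordered variable pairs over p variables.

    Parameters
    ----------
    p
        Number of variables (vertices of the causal graph); must be >= 2.
    include_diagonal
        If True, self-pairs (i, i) are indexed too, so that m = p**2 and the
        pair set corresponds to every entry of a p x p adjacency matrix.
    """
    return PairIndexer(p=p, include_diagonal=include_diagonal)
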