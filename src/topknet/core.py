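"""Core data model: candidate-edge universes, gold standards, predictions, ensembles.

A gene regulatory network (GRN) is a directed graph of transcription-factor
(regulator) to target-gene links.  Inference algorithms emit ranked edge
predictions over a fixed *candidate-edge universe*: every ordered
(regulator, target) pair with self-loops excluded (or every unordered pair
in undirected mode).  All downstream computation — rank aggregation,
evaluation, diversity — is vectorized over this universe, so its edge
ordering must be deterministic; we fix it lexicographically by
(regulator, target).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

Edge = tuple[str, str]


class TopkNetError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(TopkNetError):
    """Semantically invalid input (bad parameters, universe mismatches...)."""


class ParseError(TopkNetError):
    """Malformed input file; the message names the offending location."""


class StateError(TopkNetError):
    """Operation applied to an object in the wrong state."""


def _check_gene_list(genes: Sequence[str], what: str) -> tuple[str, ...]:
    if len(genes) == 0:
        raise ValidationError(f"{what} list must be non-empty")
    out = tuple(str(g) for g in genes)
    for g in out:
        if not g:
            raise ValidationError(f"{what} list contains an empty identifier")
    if len(set(out)) != len(out):
        dupes = sorted({g for g in out if list(out).count(g) > 1})
        raise ValidationError(f"duplicate identifiers in {what} list: {dupes}")
    return out


@dataclass
class EdgeUniverse:
    """All candidate regulatory edges under consideration.

    ``edges`` is the lexicographically sorted tuple of candidate
    (regulator, target) pairs; its ordering defines the column ordering of
    every rank matrix and score matrix in the package.
    """

    regulators: tuple[str, ...]
    targets: tuple[str, ...]
    directed: bool
    edges: tuple[Edge, ...]
    _index: dict[Edge, int] | None = field(default=None, repr=False, compare=False)

    @property
    def size(self) -> int:
        """Number of candidate edges, T."""
        return len(self.edges)

    @property
    def index(self) -> dict[Edge, int]:
        if self._index is None:
            self._index = {e: i for i, e in enumerate(self.edges)}
        return self._index

    def index_of(self, edge: Edge) -> int:
        try:
            return self.index[edge]
        except KeyError:
            raise ValidationError(f"edge {edge!r} is not in the candidate universe") from None

    def __contains__(self, edge: object) -> bool:
        return edge in self.index

    def canonical(self, regulator: str, target: str) -> Edge:
        """Canonical form of an edge: as-is when directed, sorted otherwise."""
        if self.directed or regulator <= target:
            return (regulator, target)
        return (target, regulator)


def build_edge_universe(
    regulators: Sequence[str], targets: Sequence[str], directed: bool = True
) -> EdgeUniverse:
    """Enumerate all candidate edges between regulators and targets.

    Self-loops (g, g) are excluded.  In directed mode every ordered pair
    (r, t) with r != t is a candidate; in undirected mode each unordered
    pair appears once, canonicalized lexicographically.
    """
    regs = _check_gene_list(regulators, "regulator")
    tgts = _check_gene_list(targets, "target")
    if directed:
        edges = sorted((r, t) for r in regs for t in tgts if r != t)
    else:
        seen = {tuple(sorted((r, t))) for r in regs for t in tgts if r != t}
        edges = sorted(seen)
    return EdgeUniverse(regs, tgts, directed, tuple(edges))


@dataclass
class GoldStandard:
    """A candidate universe plus the subset of edges known to be true links.

    Negatives are implicitly ``universe.edges`` minus ``true_edges``; edges
    a gold-standard file labels 0 explicitly are kept in
    ``explicit_negatives`` for provenance but carry no extra semantics.
    """

    universe: EdgeUniverse
    true_edges: frozenset[Edge]
    explicit_negatives: frozenset[Edge] = frozenset()
    _labels: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        unknown = [e for e in self.true_edges if e not in self.universe]
        if unknown:
            raise ValidationError(f"true edges outside the universe: {sorted(unknown)[:5]}")
        n_true = len(self.true_edges)
        if n_true == 0 or n_true >= self.universe.size:
            raise ValidationError(
                "gold standard is not evaluable: needs 0 < |true edges| < |candidate edges| "
                f"(got {n_true} of {self.universe.size})"
            )

    @property
    def labels(self) -> np.ndarray:
        """Boolean vector over universe.edges: True where the edge is a true link."""
        if self._labels is None:
            self._labels = np.fromiter(
                (e in self.true_edges for e in self.universe.edges),
                dtype=bool,
                count=self.universe.size,
            )
        return self._labels


@dataclass
class PredictionList:
    """One algorithm's ranked edge predictions: edges with non-increasing scores."""

    algorithm_id: str
    edges: list[Edge]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.edges) != self.scores.size:
            raise ValidationError("prediction edges and scores differ in length")
        if self.scores.size and np.any(np.diff(self.scores) > 0):
            raise ValidationError(
                f"prediction list {self.algorithm_id!r}: scores must be non-increasing"
            )
        if len(set(self.edges)) != len(self.edges):
            raise ValidationError(f"prediction list {self.algorithm_id!r}: duplicate edges")

    def __len__(self) -> int:
        return len(self.edges)

    @property
    def entries(self) -> list[tuple[Edge, float]]:
        return list(zip(self.edges, self.scores.tolist()))


@dataclass
class AlgorithmEnsemble:
    """M algorithms' rank values over a shared universe (M x T matrix).

    ``rank_matrix[a, e]`` is algorithm a's rank value for edge e (1 = most
    confident; midranks for ties; truncated lists filled at (L+1+T)/2).
    ``confidence_matrix`` optionally holds the raw scores (0 for unlisted
    edges) for diversity analyses on unnormalized confidences.
    """

    algorithm_ids: tuple[str, ...]
    universe: EdgeUniverse
    rank_matrix: np.ndarray
    confidence_matrix: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.rank_matrix = np.asarray(self.rank_matrix, dtype=float)
        m, t = self.rank_matrix.shape
        if m != len(self.algorithm_ids):
            raise ValidationError("rank matrix row count does not match algorithm ids")
        if t != self.universe.size:
            raise ValidationError("rank matrix column count does not match universe size")
        if m < 1:
            raise ValidationError("ensemble needs at least one algorithm")
        if len(set(self.algorithm_ids)) != m:
            raise ValidationError("duplicate algorithm ids in ensemble")

    @property
    def n_algorithms(self) -> int:
        return len(self.algorithm_ids)


def pair_indices(m: int) -> list[tuple[int, int]]:
    """All unordered index pairs (i, j), i < j, in row-major order."""
    if m < 2:
        raise ValidationError(f"need at least 2 algorithms to form pairs (got {m})")
    return [(i, j) for i in range(m) for j in range(i + 1, m)]


def ensemble_pairs(ensemble: AlgorithmEnsemble) -> list[tuple[str, str]]:
    """All M(M-1)/2 unordered algorithm pairs, in deterministic order.

    The order (lexicographic by algorithm index) matches the pair-vector
    flattening used by the diversity module, so distances and pairs line up.
    """
    ids = ensemble.algorithm_ids
    return [(ids[i], ids[j]) for i, j in pair_indices(len(ids))]
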