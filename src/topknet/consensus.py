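"""Rank-value transforms and consensus aggregation (TopkNet, community prediction).

Each inference algorithm's confidence scores are first converted to rank
values (1 = most confident, midranks for ties, a shared fill rank for edges
missing from a truncated list).  Consensus then aggregates the M
per-algorithm rank values of each candidate edge:

* TopkNet assigns the k-th best (numerically k-th smallest) rank value;
  Top1Net is the element-wise minimum, TopMNet the maximum.
* Community prediction assigns the arithmetic mean of the rank values.

Working on ranks rather than raw scores makes heterogeneous score scales
commensurable.  The aggregated values are finalized back into midranks
1..T plus an exported confidence in (0, 1] for serialization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .core import (
    AlgorithmEnsemble,
    EdgeUniverse,
    PredictionList,
    StateError,
    ValidationError,
)


@dataclass
class RankVector:
    """One algorithm's rank value for every edge in the universe.

    Listed edges carry midranks of their positions in the sorted prediction
    list; the L' = T - L unlisted edges all tie beyond position L and share
    ``fill_rank`` = (L + 1 + T) / 2, the midrank of positions L+1..T.  The
    total therefore always sums to T(T+1)/2.
    """

    algorithm_id: str
    universe: EdgeUniverse
    ranks: np.ndarray
    fill_rank: float

    def __post_init__(self) -> None:
        self.ranks = np.asarray(self.ranks, dtype=float)
        if self.ranks.shape != (self.universe.size,):
            raise ValidationError("rank vector length does not match universe size")


@dataclass
class ConsensusResult:
    """Aggregated rank values for one consensus method, plus the final ranking.

    ``consensus_values`` are the raw aggregated values; ``final_ranks`` are
    their midranks 1..T (smaller aggregated value = better final rank) and
    ``exported_confidence`` = 1 - (final_rank - 1)/T maps them into (0, 1]
    for DREAM-style prediction files.
    """

    method: str
    universe: EdgeUniverse
    consensus_values: np.ndarray
    k: int | None = None
    final_ranks: np.ndarray | None = None
    exported_confidence: np.ndarray | None = None

    @property
    def finalized(self) -> bool:
        return self.final_ranks is not None and self.exported_confidence is not None

    def require_finalized(self) -> None:
        if not self.finalized:
            raise StateError("consensus result has not been finalized")


def to_rank_vector(prediction: PredictionList, universe: EdgeUniverse) -> RankVector:
    """Convert a (possibly truncated) prediction list into a full rank vector."""
    t = universe.size
    n_listed = len(prediction)
    if n_listed > t:
        raise ValidationError(
            f"prediction list {prediction.algorithm_id!r} has {n_listed} edges "
            f"but the universe has only {t}"
        )
    fill = (n_listed + 1 + t) / 2.0
    ranks = np.full(t, fill, dtype=float)
    if n_listed:
        idx = np.fromiter(
            (universe.index_of(e) for e in prediction.edges), dtype=np.intp, count=n_listed
        )
        ranks[idx] = rankdata(-prediction.scores, method="average")
    return RankVector(prediction.algorithm_id, universe, ranks, fill)


def build_ensemble(
    predictions: Sequence[PredictionList], universe: EdgeUniverse
) -> AlgorithmEnsemble:
    """Assemble per-algorithm prediction lists into a shared rank matrix.

    Also records the raw confidence scores (unlisted edges scored 0) so
    diversity analyses can optionally operate on unnormalized confidences.
    """
    if not predictions:
        raise ValidationError("ensemble needs at least one prediction list")
    t = universe.size
    rank_rows = []
    conf = np.zeros((len(predictions), t))
    for a, pred in enumerate(predictions):
        rank_rows.append(to_rank_vector(pred, universe).ranks)
        if len(pred):
            idx = [universe.index_of(e) for e in pred.edges]
            conf[a, idx] = pred.scores
    ids = tuple(p.algorithm_id for p in predictions)
    return AlgorithmEnsemble(ids, universe, np.vstack(rank_rows), conf)


def finalize_ranking(consensus_values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Midrank the aggregated values and derive an exportable confidence.

    Returns (final_ranks, exported_confidence) with confidence
    1 - (rank - 1)/T, strictly decreasing in rank and confined to (0, 1].
    """
    values = np.asarray(consensus_values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValidationError("consensus values must be finite")
    final_ranks = rankdata(values, method="average")
    confidence = 1.0 - (final_ranks - 1.0) / values.size
    return final_ranks, confidence


def _finalize(result: ConsensusResult) -> ConsensusResult:
    result.final_ranks, result.exported_confidence = finalize_ranking(result.consensus_values)
    return result


def topknet(ensemble: AlgorithmEnsemble, k: int) -> ConsensusResult:
    """Order-statistic consensus: each edge gets its k-th best rank value.

    "k-th best" means the k-th smallest numeric rank among the M algorithms,
    so k=1 is the most optimistic consensus (element-wise minimum) and k=M
    the most conservative (maximum).
    """
    m = ensemble.n_algorithms
    if not 1 <= k <= m:
        raise ValidationError(f"k must satisfy 1 <= k <= {m} (got {k})")
    values = np.sort(ensemble.rank_matrix, axis=0)[k - 1]
    return _finalize(ConsensusResult("topknet", ensemble.universe, values, k=k))


def community(ensemble: AlgorithmEnsemble) -> ConsensusResult:
    """Mean-rank consensus: each edge gets the mean of its M rank values."""
    values = ensemble.rank_matrix.mean(axis=0)
    return _finalize(ConsensusResult("community", ensemble.universe, values))
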