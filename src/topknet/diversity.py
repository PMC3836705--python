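"""Quantifying diversity among inference algorithms.

Two distances over algorithms' edge-score vectors:

* EUC distance — plain Euclidean distance between two algorithms' length-T
  score vectors.
* PCA distance — Euclidean distance between the algorithms' coordinates on
  the 2nd and 3rd principal components of the ensemble score matrix
  (algorithms are observations, edges are variables; covariance PCA, i.e.
  columns centered but not scaled).  The 1st component mostly captures
  overall confidence level, so discarding it highlights *how* algorithms
  differ rather than how confident they are.

Because raw confidences from heterogeneous algorithms live on
incommensurate scales, the default score vector is rank-normalized:
score = 1 - (rank - 1)/(T - 1), mapping the best rank to 1 and the worst
to 0.  High- and low-diversity algorithm pairs are the top and bottom
``fraction`` (default 10%, rounded up) of pairs by distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .core import AlgorithmEnsemble, ValidationError, pair_indices


@dataclass
class DiversityMatrix:
    """Symmetric M x M algorithm-distance matrix and its flattened pair vector.

    ``pair_vector`` lists distances for the M(M-1)/2 unordered pairs in the
    same (i < j, row-major) order as :func:`topknet.core.ensemble_pairs`.
    """

    metric: str  # "EUC" or "PCA"
    algorithms: tuple[str, ...]
    dist: np.ndarray
    pair_vector: np.ndarray
    normalization: str  # "rank_normalized" or "raw"
    components: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.dist = np.asarray(self.dist, dtype=float)
        m = len(self.algorithms)
        if self.dist.shape != (m, m):
            raise ValidationError("distance matrix shape does not match algorithm count")
        if not np.allclose(self.dist, self.dist.T):
            raise ValidationError("distance matrix must be symmetric")
        if np.any(np.diag(self.dist) != 0):
            raise ValidationError("distance matrix diagonal must be zero")
        if np.any(self.dist < 0) or not np.all(np.isfinite(self.dist)):
            raise ValidationError("distances must be finite and non-negative")

    @property
    def pairs(self) -> list[tuple[str, str]]:
        ids = self.algorithms
        return [(ids[i], ids[j]) for i, j in pair_indices(len(ids))]


def score_vectors(ensemble: AlgorithmEnsemble, normalization: str = "rank_normalized") -> np.ndarray:
    """M x T score matrix used as input to the distances.

    ``rank_normalized`` maps each rank to 1 - (rank - 1)/(T - 1); ``raw``
    returns the stored confidence scores (unlisted edges are 0), which is
    only available when the ensemble was built from prediction lists.
    """
    t = ensemble.universe.size
    if normalization == "rank_normalized":
        if t < 2:
            raise ValidationError("rank normalization needs a universe with at least 2 edges")
        return 1.0 - (ensemble.rank_matrix - 1.0) / (t - 1.0)
    if normalization == "raw":
        if ensemble.confidence_matrix is None:
            raise ValidationError("raw scores are unavailable for this ensemble")
        return np.asarray(ensemble.confidence_matrix, dtype=float)
    raise ValidationError(f"unknown normalization {normalization!r}")


def euc_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Euclidean distance between two equal-length score vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 1:
        raise ValidationError("score vectors must be 1-D and of equal, non-zero length")
    return float(np.sqrt(((x - y) ** 2).sum()))


def _matrix_from_pairs(
    metric: str,
    algorithms: tuple[str, ...],
    pair_vector: np.ndarray,
    normalization: str,
    components: np.ndarray | None = None,
) -> DiversityMatrix:
    return DiversityMatrix(
        metric=metric,
        algorithms=algorithms,
        dist=squareform(pair_vector),
        pair_vector=pair_vector,
        normalization=normalization,
        components=components,
    )


def euc_distances(
    score_matrix: np.ndarray,
    algorithms: tuple[str, ...],
    normalization: str = "rank_normalized",
) -> DiversityMatrix:
    """EUC distance for every unordered pair of algorithm rows."""
    x = np.asarray(score_matrix, dtype=float)
    if x.shape[0] != len(algorithms):
        raise ValidationError("score matrix rows do not match algorithm ids")
    if x.shape[0] < 2:
        raise ValidationError("need at least 2 algorithms for pairwise distances")
    return _matrix_from_pairs("EUC", tuple(algorithms), pdist(x, "euclidean"), normalization)


def pca_components(score_matrix: np.ndarray) -> np.ndarray:
    """Coordinates of each algorithm on the 2nd and 3rd principal components.

    Covariance PCA on the M x T score matrix (algorithms = observations):
    columns are centered but not scaled, components ordered by decreasing
    variance.  Component signs are canonicalized so the largest-magnitude
    loading of each component is positive, making the coordinates (and
    hence distances) deterministic despite the sign indeterminacy of PCA.
    Components with (numerically) zero variance contribute exactly zero.
    """
    x = np.asarray(score_matrix, dtype=float)
    centered = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    scores = u * s
    # kill numerically-zero components; tol mirrors numpy's matrix_rank default
    tol = s[0] * max(centered.shape) * np.finfo(float).eps if s.size else 0.0
    scores[:, s <= tol] = 0.0
    for j in range(scores.shape[1]):
        lead = np.argmax(np.abs(vt[j]))
        if vt[j, lead] < 0:
            scores[:, j] = -scores[:, j]
    coords = np.zeros((x.shape[0], 2))
    for out_col, comp in enumerate((1, 2)):
        if comp < scores.shape[1]:
            coords[:, out_col] = scores[:, comp]
    return coords


def pca_distances(
    score_matrix: np.ndarray,
    algorithms: tuple[str, ...],
    normalization: str = "rank_normalized",
) -> DiversityMatrix:
    """Pairwise distances in the (PC2, PC3) plane of the ensemble score matrix."""
    x = np.asarray(score_matrix, dtype=float)
    if x.shape[0] != len(algorithms):
        raise ValidationError("score matrix rows do not match algorithm ids")
    if x.shape[0] < 3:
        raise ValidationError(
            f"PCA distance needs at least 3 algorithms so PC3 exists (got {x.shape[0]})"
        )
    coords = pca_components(x)
    return _matrix_from_pairs(
        "PCA", tuple(algorithms), pdist(coords, "euclidean"), normalization, coords
    )


def classify_pairs(
    d: DiversityMatrix, fraction: float = 0.1
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Split algorithm pairs into the high- and low-diversity extremes.

    Selects ceil(fraction * n_pairs) pairs from each end of the distance
    distribution (e.g. 45 pairs at fraction 0.1 give 5 high and 5 low).
    Ties are broken by pair order, so the selection is deterministic.
    """
    if not 0 < fraction <= 0.5:
        raise ValidationError(f"fraction must lie in (0, 0.5] (got {fraction})")
    pv = np.asarray(d.pair_vector, dtype=float)
    n_pairs = pv.size
    n_sel = math.ceil(fraction * n_pairs)
    pairs = d.pairs
    order_high = np.lexsort((np.arange(n_pairs), -pv))
    order_low = np.lexsort((np.arange(n_pairs), pv))
    high = [pairs[i] for i in order_high[:n_sel]]
    low = [pairs[i] for i in order_low[:n_sel]]
    return high, low


def write_diversity_matrix(d: DiversityMatrix, destination=None):
    """Square TSV with algorithm ids as header row and first column."""
    from pathlib import Path

    lines = ["\t" + "\t".join(d.algorithms) + "\n"]
    for alg, row in zip(d.algorithms, d.dist):
        lines.append(alg + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")
    text = "".join(lines)
    if destination is None:
        return text
    Path(destination).write_text(text, encoding="utf-8")
    return None


def write_pair_vector(d: DiversityMatrix, destination=None):
    """3-column TSV (algorithm_i, algorithm_j, distance) in pair order."""
    from pathlib import Path

    text = "".join(
        f"{a}\t{b}\t{v:.10g}\n" for (a, b), v in zip(d.pairs, d.pair_vector)
    )
    if destination is None:
        return text
    Path(destination).write_text(text, encoding="utf-8")
    return None


def read_pair_vector(source, metric: str = "EUC", normalization: str = "rank_normalized") -> DiversityMatrix:
    """Rebuild a DiversityMatrix from a 3-column pair TSV written by this module."""
    from .dream_io import _open_lines, _parse_score, _split3

    ids: list[str] = []
    entries: list[tuple[str, str, float]] = []
    for lineno, line in _open_lines(source):
        a, b, v = _split3(line, lineno)
        entries.append((a, b, _parse_score(v, lineno)))
        for alg in (a, b):
            if alg not in ids:
                ids.append(alg)
    m = len(ids)
    expected = [(ids[i], ids[j]) for i, j in pair_indices(m)] if m >= 2 else []
    if [(a, b) for a, b, _ in entries] != expected:
        raise ValidationError("pair vector file is not in canonical pair order")
    pv = np.array([v for _, _, v in entries])
    return _matrix_from_pairs(metric, tuple(ids), pv, normalization)
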