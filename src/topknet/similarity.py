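"""Similarity between expression datasets via algorithm-diversity fingerprints.

Running the same ensemble of M inference algorithms on two expression
datasets yields, for each dataset, a vector of M(M-1)/2 pairwise algorithm
distances.  Dataset similarity S(da1, da2) is the Spearman correlation of
those two vectors: datasets on which the algorithms disagree in similar
*patterns* are similar, regardless of the absolute distance scale.  A high
similarity justifies transferring the algorithms found optimal on a known
(gold-standard-bearing) dataset to an unknown one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.stats import spearmanr

from .core import ValidationError
from .diversity import DiversityMatrix
from .evaluation import EvaluationReport, select_optimal_algorithms


@dataclass
class SimilarityResult:
    """Spearman similarity between two datasets' algorithm-distance vectors.

    ``status`` is "ok" when rho is defined and "undefined" when either
    distance vector is constant (zero rank variance), in which case ``rho``
    is None rather than an arbitrary number.
    """

    dataset_a: str
    dataset_b: str
    metric: str
    rho: float | None
    status: str
    pair_vectors: tuple[np.ndarray, np.ndarray]

    @property
    def n_pairs(self) -> int:
        return self.pair_vectors[0].size

    def to_dict(self) -> dict:
        return {
            "dataset_a": self.dataset_a,
            "dataset_b": self.dataset_b,
            "metric": self.metric,
            "rho": self.rho,
            "status": self.status,
            "n_pairs": self.n_pairs,
        }


def dataset_similarity(
    div_a: DiversityMatrix,
    div_b: DiversityMatrix,
    dataset_a: str = "dataset_a",
    dataset_b: str = "dataset_b",
) -> SimilarityResult:
    """Spearman correlation (midrank ties) of two pair-distance vectors.

    Both diversity matrices must come from the same algorithm ensemble
    (identical ids in identical order) and the same distance metric, so the
    pair vectors are aligned element-for-element.
    """
    if div_a.algorithms != div_b.algorithms:
        raise ValidationError("diversity matrices were computed over different ensembles")
    if div_a.metric != div_b.metric:
        raise ValidationError(
            f"diversity metrics differ: {div_a.metric!r} vs {div_b.metric!r}"
        )
    va = np.asarray(div_a.pair_vector, dtype=float)
    vb = np.asarray(div_b.pair_vector, dtype=float)
    if va.size != vb.size or va.size < 2:
        raise ValidationError("pair vectors must have equal length >= 2")
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        return SimilarityResult(dataset_a, dataset_b, div_a.metric, None, "undefined", (va, vb))
    if np.array_equal(va, vb):
        rho = 1.0  # exact self-similarity, no round-off
    else:
        rho = float(np.clip(spearmanr(va, vb).statistic, -1.0, 1.0))
    return SimilarityResult(dataset_a, dataset_b, div_a.metric, rho, "ok", (va, vb))


def recommend_transfer(
    known_reports: Mapping[str, Mapping[str, EvaluationReport]],
    similarities: Mapping[str, SimilarityResult],
    count: int = 10,
) -> tuple[str, list[str]]:
    """Pick the known dataset most similar to the unknown one; return its
    top-``count`` algorithms by AUC-PR.

    ``known_reports`` maps dataset label -> (algorithm id -> report);
    ``similarities`` maps dataset label -> similarity against the unknown
    dataset.  Ties in rho (and undefined rho, ranked lowest) are broken by
    dataset label; a single known dataset is chosen regardless of rho.
    """
    if not known_reports:
        raise ValidationError("no known datasets to transfer from")
    missing = set(known_reports) - set(similarities)
    if missing:
        raise ValidationError(f"missing similarity results for datasets: {sorted(missing)}")

    def sort_key(label: str) -> tuple[float, str]:
        rho = similarities[label].rho
        return (-(rho if rho is not None else -np.inf), label)

    chosen = min(known_reports, key=sort_key)
    return chosen, select_optimal_algorithms(known_reports[chosen], count)
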