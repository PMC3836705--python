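"""DREAM-style evaluation of ranked edge predictions against a gold standard.

A ranked prediction is swept over every distinct rank-value threshold:
edges ranked at or better than the threshold are called positive.  From the
resulting confusion counts we build precision/recall and ROC curves
(tied ranks enter as one block, so no ordering credit is granted within a
tie), integrate them trapezoidally into AUC-PR and AUC-ROC, and take the
best F-score over thresholds.  Statistical significance is assessed with a
seeded Monte-Carlo null — random permutations of the T rank values — giving
empirical p-values p = (b + 1)/(N + 1); the overall score across benchmark
networks is OS = 0.5 (p1 + p2) with p1, p2 the means of the -log10 AUC-PR
and AUC-ROC p-values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
from scipy.stats import mannwhitneyu, rankdata

from .core import GoldStandard, ValidationError
from .consensus import ConsensusResult, RankVector

Ranked = Union[ConsensusResult, RankVector, np.ndarray]


def _ranks_of(result: Ranked, gold: GoldStandard) -> np.ndarray:
    if isinstance(result, ConsensusResult):
        result.require_finalized()
        universe, ranks = result.universe, result.final_ranks
    elif isinstance(result, RankVector):
        universe, ranks = result.universe, result.ranks
    else:
        ranks = np.asarray(result, dtype=float)
        universe = gold.universe
    if universe is not gold.universe and universe.edges != gold.universe.edges:
        raise ValidationError("prediction and gold standard are over different universes")
    if ranks.shape != (gold.universe.size,):
        raise ValidationError("rank vector length does not match the gold-standard universe")
    return ranks


@dataclass(frozen=True)
class ConfusionCounts:
    """Confusion counts at one rank threshold; totals are structurally checked."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class NullSpec:
    """Provenance of a Monte-Carlo null: number of draws and RNG seed."""

    n_draws: int
    seed: int


@dataclass
class EvaluationReport:
    """Curves and summary metrics for one prediction against one gold standard."""

    auc_pr: float
    auc_roc: float
    max_fscore: float
    pr_curve: np.ndarray
    roc_curve: np.ndarray
    thresholds: np.ndarray
    pvalue_aucpr: float | None = None
    pvalue_aucroc: float | None = None
    null_spec: NullSpec | None = None
    algorithm_id: str | None = None

    def to_dict(self) -> dict:
        out = {
            "auc_pr": self.auc_pr,
            "auc_roc": self.auc_roc,
            "max_fscore": self.max_fscore,
            "pvalue_aucpr": self.pvalue_aucpr,
            "pvalue_aucroc": self.pvalue_aucroc,
        }
        if self.null_spec is not None:
            out["null_spec"] = {"n_draws": self.null_spec.n_draws, "seed": self.null_spec.seed}
        if self.pvalue_aucpr is not None and self.pvalue_aucroc is not None:
            out["overall_score"] = overall_score([self]).score
        if self.algorithm_id is not None:
            out["algorithm_id"] = self.algorithm_id
        return out


@dataclass(frozen=True)
class OverallScore:
    """OS = 0.5 (p1 + p2), p1/p2 = mean -log10 AUC-PR / AUC-ROC p-values."""

    p1: float
    p2: float
    score: float


def confusion_at_threshold(
    result: Ranked, gold: GoldStandard, threshold: float
) -> ConfusionCounts:
    """Count TP/FP/TN/FN calling edges with rank <= threshold positive."""
    ranks = _ranks_of(result, gold)
    y = gold.labels
    positive = ranks <= threshold
    tp = int(np.count_nonzero(positive & y))
    fp = int(np.count_nonzero(positive & ~y))
    fn = int(np.count_nonzero(~positive & y))
    tn = int(np.count_nonzero(~positive & ~y))
    return ConfusionCounts(tp, fp, tn, fn)


def precision_recall(c: ConfusionCounts) -> tuple[float, float]:
    """precision = TP/(TP+FP) (1 at zero calls, the curve anchor); recall = TP/(TP+FN)."""
    if c.tp + c.fn == 0:
        raise ValidationError("gold standard has no true edges; recall is undefined")
    precision = 1.0 if c.tp + c.fp == 0 else c.tp / (c.tp + c.fp)
    recall = c.tp / (c.tp + c.fn)
    return precision, recall


def threshold_sweep(result: Ranked, gold: GoldStandard) -> dict[str, np.ndarray]:
    """One row per distinct rank value, ascending: counts, precision, recall, rates."""
    ranks = _ranks_of(result, gold)
    y = gold.labels
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("gold standard must contain both true and false edges")
    order = np.argsort(ranks, kind="stable")
    sorted_ranks = ranks[order]
    sorted_y = y[order]
    _, starts = np.unique(sorted_ranks, return_index=True)
    ends = np.append(starts[1:], ranks.size) - 1  # last index of each tie block
    cum_tp = np.cumsum(sorted_y)
    tp = cum_tp[ends].astype(float)
    called = ends + 1.0
    fp = called - tp
    return {
        "threshold": sorted_ranks[ends],
        "tp": tp,
        "fp": fp,
        "fn": n_pos - tp,
        "tn": n_neg - fp,
        "precision": tp / called,
        "recall": tp / n_pos,
        "fpr": fp / n_neg,
        "tpr": tp / n_pos,
    }


def curves(result: Ranked, gold: GoldStandard) -> tuple[np.ndarray, np.ndarray]:
    """(PR, ROC) staircases: one point per distinct rank value plus anchors.

    PR points are (recall, precision) anchored at (0, 1); ROC points are
    (FPR, TPR) anchored at (0, 0) and ending at (1, 1).
    """
    sweep = threshold_sweep(result, gold)
    pr = np.vstack([[0.0, 1.0], np.column_stack([sweep["recall"], sweep["precision"]])])
    roc = np.vstack([[0.0, 0.0], np.column_stack([sweep["fpr"], sweep["tpr"]])])
    return pr, roc


def auc(curve: np.ndarray) -> float:
    """Trapezoidal area under an (x, y) curve with non-decreasing x."""
    points = np.asarray(curve, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2 or points.shape[0] < 2:
        raise ValidationError("curve must be an (n >= 2) x 2 array of points")
    x, y = points[:, 0], points[:, 1]
    if np.any(np.diff(x) < 0):
        raise ValidationError("curve x-coordinates must be non-decreasing")
    return float(np.trapezoid(y, x))


def max_fscore(result: Ranked, gold: GoldStandard) -> float:
    """Best harmonic mean of precision and recall over all rank thresholds."""
    sweep = threshold_sweep(result, gold)
    p, r = sweep["precision"], sweep["recall"]
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(p + r > 0, 2 * p * r / (p + r), 0.0)
    return float(f.max())


def _null_aucs(labels: np.ndarray, which: str, n_draws: int, seed: int) -> np.ndarray:
    """AUCs of n_draws random permutations of the T ranks (untied ranking 1..T)."""
    rng = np.random.default_rng(seed)
    t = labels.size
    n_pos = int(labels.sum())
    n_neg = t - n_pos
    positions = np.arange(1, t + 1, dtype=float)
    out = np.empty(n_draws)
    for i in range(n_draws):
        yp = rng.permutation(labels)
        cum_tp = np.cumsum(yp)
        if which == "ROC":
            # pairs (true edge ranked before false edge) / all pairs
            cum_fp = positions - cum_tp
            out[i] = float(((n_neg - cum_fp)[yp]).sum()) / (n_pos * n_neg)
        else:
            rec = np.concatenate([[0.0], cum_tp / n_pos])
            prec = np.concatenate([[1.0], cum_tp / positions])
            out[i] = float(np.trapezoid(prec, rec))
    return out


def empirical_pvalue(
    observed_auc: float,
    gold: GoldStandard,
    which: str,
    n_draws: int = 1000,
    seed: int = 0,
) -> float:
    """Monte-Carlo probability of reaching the observed AUC by random scoring.

    Draws ``n_draws`` uniformly random permutations of the T ranks, scores
    each against the gold standard, and returns the add-one estimate
    p = (b + 1)/(N + 1) with b the number of null AUCs >= observed.
    Deterministic given the seed; p always lies in [1/(N+1), 1].
    """
    if which not in ("PR", "ROC"):
        raise ValidationError(f"which must be 'PR' or 'ROC' (got {which!r})")
    if n_draws < 1:
        raise ValidationError(f"n_draws must be >= 1 (got {n_draws})")
    if not math.isfinite(observed_auc):
        raise ValidationError("observed AUC must be finite")
    null = _null_aucs(gold.labels, which, n_draws, seed)
    b = int(np.count_nonzero(null >= observed_auc))
    return (b + 1) / (n_draws + 1)


def evaluate(
    result: Ranked,
    gold: GoldStandard,
    n_null: int = 1000,
    seed: int = 0,
    with_pvalues: bool = True,
    algorithm_id: str | None = None,
) -> EvaluationReport:
    """Full evaluation: curves, AUCs, max F-score and (optionally) p-values."""
    sweep = threshold_sweep(result, gold)
    pr, roc = curves(result, gold)
    auc_pr, auc_roc = auc(pr), auc(roc)
    report = EvaluationReport(
        auc_pr=auc_pr,
        auc_roc=auc_roc,
        max_fscore=max_fscore(result, gold),
        pr_curve=pr,
        roc_curve=roc,
        thresholds=sweep["threshold"],
        algorithm_id=algorithm_id,
    )
    if with_pvalues:
        report.pvalue_aucpr = empirical_pvalue(auc_pr, gold, "PR", n_null, seed)
        report.pvalue_aucroc = empirical_pvalue(auc_roc, gold, "ROC", n_null, seed)
        report.null_spec = NullSpec(n_null, seed)
    return report


def overall_score(reports: Sequence[EvaluationReport]) -> OverallScore:
    """Aggregate per-network p-values into the overall score OS = 0.5 (p1 + p2)."""
    if not reports:
        raise ValidationError("overall score needs at least one report")
    for rep in reports:
        for p in (rep.pvalue_aucpr, rep.pvalue_aucroc):
            if p is None or not 0 < p <= 1:
                raise ValidationError(f"p-values must lie in (0, 1] (got {p!r})")
    p1 = float(np.mean([-math.log10(rep.pvalue_aucpr) for rep in reports]))
    p2 = float(np.mean([-math.log10(rep.pvalue_aucroc) for rep in reports]))
    return OverallScore(p1, p2, 0.5 * (p1 + p2))


def select_optimal_algorithms(
    reports: Union[Mapping[str, EvaluationReport], Iterable[tuple[str, float]]],
    count: int,
) -> list[str]:
    """Ids of the ``count`` algorithms with highest AUC-PR (ties by id)."""
    if isinstance(reports, Mapping):
        scored = [(alg, rep.auc_pr) for alg, rep in reports.items()]
    else:
        scored = [(alg, float(a)) for alg, a in reports]
    if count < 1 or count > len(scored):
        raise ValidationError(
            f"count must be between 1 and the number of algorithms ({len(scored)}), got {count}"
        )
    scored.sort(key=lambda item: (-item[1], item[0]))
    return [alg for alg, _ in scored[:count]]


def compare_groups(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Wilcoxon rank-sum comparison of two score groups.

    Returns (rank-sum statistic of group a, p-value).  When both groups
    have at most 10 observations the null is enumerated exactly over all
    label assignments (midranks handle ties); otherwise the normal
    approximation with tie correction is used.  ``alternative`` is
    "two-sided" (default) or "greater" (group a stochastically larger).
    """
    if alternative not in ("two-sided", "greater"):
        raise ValidationError(f"alternative must be 'two-sided' or 'greater' (got {alternative!r})")
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled, method="average")
    w = float(ranks[: a.size].sum())
    if a.size <= 10 and b.size <= 10:
        n = pooled.size
        mu = a.size * (n + 1) / 2.0
        count = 0
        total = 0
        for idx in combinations(range(n), a.size):
            total += 1
            w_null = ranks[list(idx)].sum()
            if alternative == "two-sided":
                extreme = abs(w_null - mu) >= abs(w - mu) - 1e-9
            else:
                extreme = w_null >= w - 1e-9
            count += extreme
        return w, count / total
    _, p = mannwhitneyu(a, b, alternative=alternative, method="asymptotic")
    return w, float(p)
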