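"""Synthetic benchmark generator for consensus network inference.

Emulates, at desk scale, the situation the consensus methods were designed
for: a known regulatory network, an ensemble of inference algorithms of
varying quality whose errors are correlated within algorithm "families",
and expression data for simple baseline scorers.

The generative model for algorithm scores is additive Gaussian: every
candidate edge e carries a latent signal z(e) ~ N(mu1, 1) if the edge is
true and N(0, 1) otherwise, shared by all algorithms.  Algorithm a in
group g scores the edge

    score_a(e) = q_a * z(e) + sqrt(1 - q_a^2) * eps_a(e),
    eps_a(e)   = sqrt(rho_g) * eta_g(e) + sqrt(1 - rho_g) * eta_a(e),

with independent standard normal eta terms.  The quality q_a in [0, 1]
dials each algorithm from pure noise (q=0, AUC-ROC ~ 0.5) to a perfect
signal reader (q=1); the within-group noise correlation rho_g makes
same-family algorithms redundant while cross-family pairs stay diverse.
All generators are bit-reproducible given the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .core import (
    AlgorithmEnsemble,
    EdgeUniverse,
    GoldStandard,
    PredictionList,
    ValidationError,
    build_edge_universe,
)
from .consensus import build_ensemble
from .dream_io import ExpressionMatrix


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic benchmark dataset.

    Defaults give a desk-scale problem (30 regulators x 200 genes, T = 5970
    candidate edges, ~119 true links) that yields stable AUCs in seconds.
    The default ensemble emulates what a "top 10 by AUC-PR" selection
    produces on real benchmarks: ten comparably strong algorithms (uniform
    quality 0.8) drawn from five methodological families of two.  Signal
    shift 2.0 puts individual algorithms in a realistic mid-accuracy
    regime, and within-family noise correlation 0.8 reflects the
    near-redundancy of same-family inference methods (two
    mutual-information-based scorers rank edges almost identically), which
    is exactly what makes cross-family pairs the diverse, complementary
    ones.
    """

    n_genes: int = 200
    n_regulators: int = 30
    edge_density: float = 0.02
    n_algorithms: int = 10
    quality: tuple[float, ...] | None = None
    groups: tuple[str, ...] | None = None
    within_group_corr: float = 0.8
    signal_shift: float = 2.0
    seed: int = 0

    def resolved_quality(self) -> np.ndarray:
        if self.quality is None:
            return np.full(self.n_algorithms, 0.8)
        return np.asarray(self.quality, dtype=float)

    def resolved_groups(self) -> tuple[str, ...]:
        if self.groups is None:
            return tuple(f"fam{a // 2 + 1}" for a in range(self.n_algorithms))
        return tuple(self.groups)

    def validate(self) -> None:
        if self.n_regulators < 1 or self.n_regulators > self.n_genes:
            raise ValidationError("need 1 <= n_regulators <= n_genes")
        if not 0 < self.edge_density < 1:
            raise ValidationError(f"edge density must lie in (0, 1), got {self.edge_density}")
        if self.n_algorithms < 1:
            raise ValidationError("need at least one algorithm")
        q = self.resolved_quality()
        if q.size != self.n_algorithms or np.any((q < 0) | (q > 1)):
            raise ValidationError("quality must give one value in [0, 1] per algorithm")
        if len(self.resolved_groups()) != self.n_algorithms:
            raise ValidationError("groups must give one label per algorithm")
        if not 0 <= self.within_group_corr < 1:
            raise ValidationError("within-group correlation must lie in [0, 1)")
        if self.signal_shift <= 0:
            raise ValidationError("signal shift must be positive")


def _gene_ids(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def generate_network(cfg: SyntheticConfig) -> GoldStandard:
    """Sample a gold-standard network: regulators x genes universe, uniform true edges."""
    cfg.validate()
    genes = _gene_ids(cfg.n_genes)
    universe = build_edge_universe(genes[: cfg.n_regulators], genes, directed=True)
    t = universe.size
    n_true = math.ceil(cfg.edge_density * t)
    if n_true == 0 or n_true >= t:
        raise ValidationError(
            f"edge density {cfg.edge_density} gives {n_true} true edges of {t}; "
            "need 0 < true < T"
        )
    rng = np.random.default_rng([cfg.seed, 11])
    chosen = rng.choice(t, size=n_true, replace=False)
    true_edges = frozenset(universe.edges[i] for i in chosen)
    return GoldStandard(universe, true_edges)


def simulate_predictions(
    gold: GoldStandard,
    cfg: SyntheticConfig,
    top_l: int | None = None,
    seed: int | None = None,
) -> list[PredictionList]:
    """Simulate one full prediction list per algorithm under the score model.

    ``seed`` overrides the config seed for the score noise only, so several
    datasets can share a network but carry independent measurement noise
    (e.g. to emulate running the same ensemble on two expression datasets).
    """
    cfg.validate()
    universe = gold.universe
    t = universe.size
    q = cfg.resolved_quality()
    groups = cfg.resolved_groups()
    rho = cfg.within_group_corr
    rng = np.random.default_rng([cfg.seed if seed is None else seed, 13])
    z = rng.normal(0.0, 1.0, t) + cfg.signal_shift * gold.labels
    group_noise = {g: rng.normal(0.0, 1.0, t) for g in dict.fromkeys(groups)}
    predictions = []
    for a in range(cfg.n_algorithms):
        eta = rng.normal(0.0, 1.0, t)
        eps = math.sqrt(rho) * group_noise[groups[a]] + math.sqrt(1.0 - rho) * eta
        scores = q[a] * z + math.sqrt(1.0 - q[a] ** 2) * eps
        order = sorted(range(t), key=lambda i: (-scores[i], universe.edges[i]))
        if top_l is not None:
            order = order[:top_l]
        predictions.append(
            PredictionList(
                f"alg{a + 1:02d}",
                [universe.edges[i] for i in order],
                scores[order],
            )
        )
    return predictions


def simulate_ensemble(
    cfg: SyntheticConfig, top_l: int | None = None, seed: int | None = None
) -> tuple[GoldStandard, AlgorithmEnsemble]:
    """Convenience: network + simulated predictions assembled into an ensemble."""
    gold = generate_network(cfg)
    preds = simulate_predictions(gold, cfg, top_l=top_l, seed=seed)
    return gold, build_ensemble(preds, gold.universe)


def worked_example_ranks() -> np.ndarray:
    """The five per-algorithm rank values of the canonical worked example.

    Five algorithms assign ranks 1, 3.5, 10, 10.5 and 12 to one regulatory
    link in a 12-edge universe; Top1Net and Top2Net assign it 1 and 3.5,
    community prediction the mean 7.4.
    """
    return np.array([1.0, 3.5, 10.0, 10.5, 12.0])


def worked_example_ensemble() -> tuple[AlgorithmEnsemble, int]:
    """A 5-algorithm, 12-edge ensemble realizing the worked-example ranks.

    Builds genuine prediction lists (with score ties where a fractional
    midrank is required) over a 4-gene directed universe and pushes them
    through the ordinary rank-conversion path, so consensus on the returned
    ensemble exercises exactly the code a real run uses.  Returns the
    ensemble and the index of the focal edge, whose per-algorithm rank
    values are (1, 3.5, 10, 10.5, 12).
    """
    genes = ["G1", "G2", "G3", "G4"]
    universe = build_edge_universe(genes, genes, directed=True)  # T = 12
    focal = universe.index_of(("G1", "G2"))
    t = universe.size
    predictions = []
    for a, target_rank in enumerate(worked_example_ranks()):
        # position scores: strictly decreasing, with a two-way tie when the
        # focal edge needs a fractional midrank
        pos_scores = [float(t - p) for p in range(t)]
        if target_rank != int(target_rank):
            lo = int(target_rank - 0.5)  # 1-based first tied position
            pos_scores[lo] = pos_scores[lo - 1]
            focal_pos = lo - 1
        else:
            focal_pos = int(target_rank) - 1
        others = [i for i in range(t) if i != focal]
        edge_at = {focal_pos: focal}
        for p in range(t):
            if p not in edge_at:
                edge_at[p] = others.pop(0)
        predictions.append(
            PredictionList(
                f"alg{a + 1}",
                [universe.edges[edge_at[p]] for p in range(t)],
                np.array(pos_scores),
            )
        )
    return build_ensemble(predictions, universe), focal


def simulate_expression(
    gold: GoldStandard, n_samples: int = 100, noise: float = 0.5, seed: int = 0
) -> ExpressionMatrix:
    """Toy linear expression data consistent with a gold-standard network.

    Regulator rows are independent standard normals; each target gene is the
    sum of its true regulators plus Gaussian noise.  Only meant to feed the
    correlation baseline scorers — no dynamics, no nonlinearity.
    """
    rng = np.random.default_rng([seed, 17])
    universe = gold.universe
    genes = sorted(set(universe.regulators) | set(universe.targets))
    reg_expr = {r: rng.normal(0.0, 1.0, n_samples) for r in universe.regulators}
    parents: dict[str, list[str]] = {}
    for r, t in gold.true_edges:
        parents.setdefault(t, []).append(r)
    rows = []
    for g in genes:
        base = reg_expr.get(g)
        if base is None:
            base = np.zeros(n_samples)
        expr = base.copy()
        for r in parents.get(g, []):
            if g not in universe.regulators:  # regulators keep their own signal
                expr = expr + reg_expr[r]
        expr = expr + noise * rng.normal(0.0, 1.0, n_samples)
        rows.append(expr)
    return ExpressionMatrix(tuple(genes), tuple(f"S{i + 1}" for i in range(n_samples)), np.array(rows))


def correlation_scorer(
    expr: ExpressionMatrix,
    universe: EdgeUniverse,
    method: str = "pearson",
    algorithm_id: str | None = None,
) -> PredictionList:
    """Baseline scorer: confidence = |correlation| of regulator and target rows.

    A stand-in for off-the-shelf inference algorithms; ``spearman`` simply
    rank-transforms the rows first.  Genes with zero expression variance get
    correlation 0 against everything.
    """
    if method not in ("pearson", "spearman"):
        raise ValidationError(f"method must be 'pearson' or 'spearman' (got {method!r})")
    needed = sorted(set(universe.regulators) | set(universe.targets))
    index = {}
    for g in needed:
        if g not in expr.genes:
            raise ValidationError(f"gene {g!r} missing from expression matrix")
        index[g] = expr.genes.index(g)
    values = expr.values
    if method == "spearman":
        values = np.apply_along_axis(rankdata, 1, values)
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    safe = np.where(norms > 0, norms, 1.0)
    unit = centered / safe[:, None]
    unit[norms == 0] = 0.0  # zero-variance rows correlate 0 with everything
    scores = np.array(
        [abs(float(unit[index[r]] @ unit[index[t]])) for r, t in universe.edges]
    )
    order = sorted(range(universe.size), key=lambda i: (-scores[i], universe.edges[i]))
    return PredictionList(
        algorithm_id or f"corr_{method}",
        [universe.edges[i] for i in order],
        scores[order],
    )
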