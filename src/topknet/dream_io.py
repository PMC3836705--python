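"""Readers and writers for DREAM-style flat files.

All files are plain tab-separated text without headers (except the
expression matrix, whose first row names the samples):

* prediction file:    regulator <TAB> target <TAB> confidence
* gold standard file: regulator <TAB> target <TAB> label in {0, 1}
* expression matrix:  header of sample ids; rows of gene id + values

Readers are strict: malformed lines raise :class:`~topknet.core.ParseError`
with a line number, and every accepted file re-serializes to a semantically
identical object.  Lines starting with '#' and blank lines are skipped.
Numbers use a decimal point only; scientific notation is accepted.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterator, Union

import numpy as np

from .core import (
    Edge,
    EdgeUniverse,
    GoldStandard,
    ParseError,
    PredictionList,
    ValidationError,
    build_edge_universe,
)
from .consensus import ConsensusResult

#: Default truncation: keep the links with the top 100,000 highest confidence
#: scores, the standard cut used for DREAM5-scale prediction files.
DEFAULT_TOP_L = 100_000

Source = Union[str, Path, IO[str]]


def _open_lines(source: Source) -> Iterator[tuple[int, str]]:
    """Yield (1-based line number, stripped line), skipping blanks and comments."""
    if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and Path(source).is_file()
    ):
        handle: IO[str] = open(source, "r", encoding="utf-8")
        close = True
    elif isinstance(source, str):
        handle = io.StringIO(source)
        close = False
    else:
        handle = source  # type: ignore[assignment]
        close = False
    try:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip()
            if not line or line.lstrip().startswith("#"):
                continue
            yield lineno, line
    finally:
        if close:
            handle.close()


def _split3(line: str, lineno: int) -> tuple[str, str, str]:
    fields = line.split("\t")
    if len(fields) != 3:
        raise ParseError(f"line {lineno}: expected 3 tab-separated fields, got {len(fields)}")
    a, b, c = (f.strip() for f in fields)
    if not a or not b or not c:
        raise ParseError(f"line {lineno}: empty field")
    return a, b, c


def _parse_score(text: str, lineno: int) -> float:
    try:
        value = float(text)
    except ValueError:
        raise ParseError(f"line {lineno}: non-numeric score {text!r}") from None
    if not math.isfinite(value):
        raise ParseError(f"line {lineno}: non-finite score {text!r}")
    return value


def read_prediction_list(
    source: Source,
    universe: EdgeUniverse,
    top_l: int = DEFAULT_TOP_L,
    algorithm_id: str = "prediction",
) -> PredictionList:
    """Read a 3-column prediction file, sort by score and truncate to top_l.

    Rows are sorted by non-increasing confidence; ties are broken
    lexicographically by edge id, and the list is cut strictly at ``top_l``
    after that tie-break, so output size is deterministic even when scores
    tie at the boundary.
    """
    if top_l < 1:
        raise ValidationError(f"top_l must be positive (got {top_l})")
    entries: list[tuple[float, Edge]] = []
    seen: set[Edge] = set()
    for lineno, line in _open_lines(source):
        reg, tgt, score_text = _split3(line, lineno)
        score = _parse_score(score_text, lineno)
        edge = universe.canonical(reg, tgt)
        if edge not in universe:
            raise ValidationError(f"line {lineno}: edge ({reg}, {tgt}) is not in the universe")
        if edge in seen:
            raise ParseError(f"line {lineno}: duplicate edge ({reg}, {tgt})")
        seen.add(edge)
        entries.append((score, edge))
    entries.sort(key=lambda se: (-se[0], se[1]))
    entries = entries[:top_l]
    return PredictionList(
        algorithm_id,
        [e for _, e in entries],
        np.array([s for s, _ in entries], dtype=float),
    )


def write_prediction_list(
    result: Union[ConsensusResult, PredictionList],
    destination: Union[str, Path, IO[str], None] = None,
    top_l: int = DEFAULT_TOP_L,
) -> str | None:
    """Serialize a finalized consensus result (or a prediction list) to TSV.

    Rows are sorted by decreasing exported confidence, ties broken
    lexicographically by edge, and truncated to ``top_l``.  When
    ``destination`` is None, the TSV text is returned instead of written.
    """
    if isinstance(result, ConsensusResult):
        result.require_finalized()
        order = sorted(
            range(result.universe.size),
            key=lambda i: (result.final_ranks[i], result.universe.edges[i]),
        )[:top_l]
        rows = [
            (result.universe.edges[i], result.exported_confidence[i]) for i in order
        ]
    else:
        order = sorted(range(len(result)), key=lambda i: (-result.scores[i], result.edges[i]))
        rows = [(result.edges[i], float(result.scores[i])) for i in order[:top_l]]
    text = "".join(f"{r}\t{t}\t{c:.10g}\n" for (r, t), c in rows)
    if destination is None:
        return text
    if isinstance(destination, (str, Path)):
        Path(destination).write_text(text, encoding="utf-8")
    else:
        destination.write(text)
    return None


def read_gold_standard(
    source: Source, universe: EdgeUniverse | None = None
) -> GoldStandard:
    """Read a 3-column gold-standard file (regulator, target, label in {0,1}).

    When no universe is supplied, one is inferred from the file itself:
    regulators are the column-1 genes, targets the union of all genes, and
    the candidate edges are all regulator x target combinations (self-loops
    excluded) — the DREAM convention of restricting candidates to TF→gene
    pairs.
    """
    labels: dict[Edge, int] = {}
    col1: set[str] = set()
    genes: set[str] = set()
    for lineno, line in _open_lines(source):
        reg, tgt, label_text = _split3(line, lineno)
        if label_text not in ("0", "1"):
            raise ParseError(f"line {lineno}: label must be 0 or 1, got {label_text!r}")
        if reg == tgt:
            raise ValidationError(f"line {lineno}: self-loop ({reg}, {tgt}) is not allowed")
        label = int(label_text)
        edge = (reg, tgt) if universe is None else universe.canonical(reg, tgt)
        if edge in labels and labels[edge] != label:
            raise ValidationError(f"line {lineno}: contradictory labels for edge ({reg}, {tgt})")
        labels[edge] = label
        col1.add(reg)
        genes.update((reg, tgt))
    if not labels:
        raise ValidationError("gold standard contains no evaluable edges")
    if universe is None:
        universe = build_edge_universe(sorted(col1), sorted(genes), directed=True)
        labels = {universe.canonical(*e): lab for e, lab in labels.items()}
    for edge in labels:
        if edge not in universe:
            raise ValidationError(f"gold-standard edge {edge!r} is not in the universe")
    true_edges = frozenset(e for e, lab in labels.items() if lab == 1)
    negatives = frozenset(e for e, lab in labels.items() if lab == 0)
    return GoldStandard(universe, true_edges, negatives)


def write_gold_standard(
    gold: GoldStandard, destination: Union[str, Path, IO[str], None] = None
) -> str | None:
    """Serialize a gold standard with a 0/1 label for every candidate edge."""
    text = "".join(
        f"{r}\t{t}\t{1 if (r, t) in gold.true_edges else 0}\n"
        for r, t in gold.universe.edges
    )
    if destination is None:
        return text
    if isinstance(destination, (str, Path)):
        Path(destination).write_text(text, encoding="utf-8")
    else:
        destination.write(text)
    return None


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of normalized (unitless) expression values."""

    genes: tuple[str, ...]
    samples: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValidationError("expression matrix shape does not match id lists")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("duplicate gene ids in expression matrix")
        if len(set(self.samples)) != len(self.samples):
            raise ValidationError("duplicate sample ids in expression matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression matrix contains non-finite values")

    def row(self, gene: str) -> np.ndarray:
        try:
            return self.values[self.genes.index(gene)]
        except ValueError:
            raise ValidationError(f"gene {gene!r} not present in expression matrix") from None


def read_expression_matrix(source: Source) -> ExpressionMatrix:
    """Read a TSV expression matrix: sample header row, gene-id first column."""
    lines = list(_open_lines(source))
    if not lines:
        raise ParseError("expression matrix file is empty")
    header_no, header = lines[0]
    samples = [f.strip() for f in header.split("\t") if f.strip()]
    if not samples:
        raise ParseError(f"line {header_no}: header row names no samples")
    if len(lines) == 1:
        raise ParseError("expression matrix has a header but no gene rows")
    genes: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in lines[1:]:
        fields = line.split("\t")
        if len(fields) != len(samples) + 1:
            raise ParseError(
                f"line {lineno}: expected {len(samples) + 1} fields, got {len(fields)}"
            )
        gene = fields[0].strip()
        if not gene:
            raise ParseError(f"line {lineno}: empty gene id")
        if gene in genes:
            raise ParseError(f"line {lineno}: duplicate gene id {gene!r}")
        values = []
        for col, text in enumerate(fields[1:], start=1):
            try:
                value = float(text)
            except ValueError:
                raise ParseError(
                    f"line {lineno}: non-numeric value {text.strip()!r} for gene {gene!r}, "
                    f"sample {samples[col - 1]!r}"
                ) from None
            if not math.isfinite(value):
                raise ParseError(
                    f"line {lineno}: non-finite value for gene {gene!r}, "
                    f"sample {samples[col - 1]!r}"
                )
            values.append(value)
        genes.append(gene)
        rows.append(values)
    return ExpressionMatrix(tuple(genes), tuple(samples), np.array(rows))


def write_curve_tsv(
    thresholds: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    x_name: str,
    y_name: str,
    destination: Union[str, Path, IO[str], None] = None,
) -> str | None:
    """Write a per-threshold curve as TSV: threshold_rank, x, y (with header)."""
    lines = [f"threshold_rank\t{x_name}\t{y_name}\n"]
    lines += [f"{t:.10g}\t{a:.10g}\t{b:.10g}\n" for t, a, b in zip(thresholds, x, y)]
    text = "".join(lines)
    if destination is None:
        return text
    if isinstance(destination, (str, Path)):
        Path(destination).write_text(text, encoding="utf-8")
    else:
        destination.write(text)
    return None


def read_run_config(source: Source) -> dict[str, str]:
    """Read a flat ``key = value`` run-configuration file (one pair per line)."""
    config: dict[str, str] = {}
    for lineno, line in _open_lines(source):
        if "=" not in line:
            raise ParseError(f"line {lineno}: expected 'key = value'")
        key, _, value = line.partition("=")
        key = key.strip()
        if not key:
            raise ParseError(f"line {lineno}: empty key")
        config[key] = value.strip()
    return config


def write_json(obj: dict, destination: Union[str, Path, IO[str]]) -> None:
    text = json.dumps(obj, indent=2, sort_keys=True) + "\n"
    if isinstance(destination, (str, Path)):
        Path(destination).write_text(text, encoding="utf-8")
    else:
        destination.write(text)
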