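"""Candidate-pair generation and significance calling.

The coarse filter removes column pairs that cannot plausibly covary (very
different conservation entropies, or mutual information outside either
column's top ranks), cutting the quadratic pair enumeration down to a
tractable candidate set before the expensive tree traversals.  The Joint
N-Best strategy then calls base pairs: a pair passes when each column's
second-best covariation score is at most ``threshold`` times its best score
*and* the two columns are reciprocal best partners — the covariation is not
just strong but unambiguous in both directions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .io import Alignment
from .scores import (ScoreMatrix, entropy_vector, mixy, pair_state_table)

logger = logging.getLogger(__name__)


@dataclass
class CandidatePair:
    col_i: int
    col_j: int
    entropy_i: float
    entropy_j: float
    mixy: float


def coarse_filter(
    alignment: Alignment,
    entropy_tol: float = 0.2,
    top_k: int = 100,
    columns: Optional[Sequence[int]] = None,
) -> list[CandidatePair]:
    """Keep pairs with similar entropies and mutually top-ranked MIxy.

    A pair (X, Y) survives iff |H(X) - H(Y)| <= ``entropy_tol`` and its
    MIxy ranks within the ``top_k`` scores of both X's and Y's partner
    lists (partner lists taken over the entropy-compatible pairs).  Columns
    with no variation carry no information and drop out naturally through
    MIxy = 0 ranks; pairs with fewer than 2 jointly informative sequences
    are skipped.  Output is sorted by (col_i, col_j) and de-duplicated.
    """
    if entropy_tol < 0:
        raise ValueError("entropy_tol must be >= 0")
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if columns is None:
        columns = range(1, alignment.n_columns + 1)
    columns = sorted(set(columns))
    H = {c: h for c, h in zip(
        columns,
        (entropy_vector(alignment)[np.array(columns) - 1]
         if columns else np.array([])),
    )}

    mi = ScoreMatrix("MIxy")
    for a_idx, x in enumerate(columns):
        for y in columns[a_idx + 1:]:
            if abs(H[x] - H[y]) > entropy_tol:
                continue
            table = pair_state_table(alignment, x, y)
            if table.n_effective < 2:
                continue
            mi.set(x, y, mixy(table))

    # rank cutoff per column: the top_k-th highest score among its partners
    kept: list[CandidatePair] = []
    rank_ok: dict[int, set[int]] = {}
    for c in mi.columns():
        ranked = mi.ranked_partners(c)
        rank_ok[c] = {p for p, _ in ranked[:top_k]}
    for (x, y), s in sorted(mi.items()):
        if y in rank_ok.get(x, ()) and x in rank_ok.get(y, ()):
            kept.append(CandidatePair(x, y, H[x], H[y], s))
    logger.info(
        "coarse filter: %d of %d entropy-compatible pairs retained",
        len(kept), len(mi),
    )
    return kept


@dataclass
class NBestResult:
    """Joint N-Best outcome for one scored pair."""

    col_i: int
    col_j: int
    method: str
    nbest_i: float
    nbest_j: float
    mutual_best: bool
    passed: bool
    single_partner_i: bool = False
    single_partner_j: bool = False


def one_directional_nbest(scores: ScoreMatrix, col: int) -> float:
    """Ratio of a column's second-highest to highest score; 0 if one partner.

    Invariant under positive rescaling of all scores.  Raises when the
    column has no scored partner or its best score is not positive.
    """
    ranked = scores.ranked_partners(col)
    if not ranked:
        raise ValueError(f"column {col} has no scored partners")
    best = ranked[0][1]
    if best <= 0:
        raise ValueError(f"column {col}: best score {best} <= 0, ratio undefined")
    if len(ranked) == 1:
        return 0.0
    return ranked[1][1] / best


def joint_nbest(scores: ScoreMatrix, threshold: float = 0.5) -> list[NBestResult]:
    """Joint N-Best calls over a score matrix.

    A pair passes iff the two columns are reciprocal best partners (ties
    broken toward the lower column index) and both columns' second-to-best
    ratios are <= ``threshold``.  Columns whose best score is non-positive
    are not callable and yield no result rows for their pairs.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    ratios: dict[int, float] = {}
    best_partner: dict[int, int] = {}
    single: dict[int, bool] = {}
    for c in scores.columns():
        ranked = scores.ranked_partners(c)
        if ranked[0][1] <= 0:
            logger.info("column %d not callable: best score <= 0", c)
            continue
        best_partner[c] = ranked[0][0]
        single[c] = len(ranked) == 1
        ratios[c] = 0.0 if single[c] else ranked[1][1] / ranked[0][1]

    results: list[NBestResult] = []
    for (i, j) in scores.pairs():
        if i not in ratios or j not in ratios:
            continue
        mutual = best_partner[i] == j and best_partner[j] == i
        passed = mutual and ratios[i] <= threshold and ratios[j] <= threshold
        results.append(NBestResult(
            i, j, scores.method, ratios[i], ratios[j], mutual, passed,
            single[i], single[j],
        ))
    return results


def passed_pairs(results: Iterable[NBestResult]) -> list[tuple[int, int]]:
    return sorted((r.col_i, r.col_j) for r in results if r.passed)


def merge_calls(
    calls_a: Iterable[tuple[int, int]],
    calls_b: Iterable[tuple[int, int]],
    label_a: str = "a",
    label_b: str = "b",
) -> dict[tuple[int, int], str]:
    """Non-redundant union of two call sets with provenance tags.

    Tags are ``"both"``, ``"<label_a>_only"`` or ``"<label_b>_only"``.
    """
    norm = lambda p: (min(p), max(p))
    a = {norm(p) for p in calls_a}
    b = {norm(p) for p in calls_b}
    merged: dict[tuple[int, int], str] = {}
    for p in sorted(a | b):
        if p in a and p in b:
            merged[p] = "both"
        elif p in a:
            merged[p] = f"{label_a}_only"
        else:
            merged[p] = f"{label_b}_only"
    return merged
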