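"""Helix extension, purity scoring, neighbor effects and call evaluation.

Helix extension grows a putative helix from covariation-supported
"nucleation" pairs: adjacent, antiparallel column pairs are accepted while
the fraction of sequences forming a canonical (Watson-Crick or wobble)
base pair at the two columns stays at or above a threshold.  This recovers
conserved base pairs that covariation alone cannot see (no variation, no
covariation).

The purity score measures how exclusively each nucleotide at a column pair
associates with a single partner: pair types are ranked by frequency and
accepted greedily when both their 5' and 3' nucleotides are unused by
already-accepted types (i.e. the type covaries with all accepted types);
the score is the summed frequency of accepted types.  The GU-plus variant
additionally credits the wobble pair G:U (U:G) alongside canonical
G:C/C:G/A:U/U:A types, since wobble pairs occur within regular helices.

Neighbor effects are column pairs with significant but non-exclusive
covariation (high one-directional N-Best ratio, moderate CPE, enough
events) that typically lie close together in the 3-D structure without
base pairing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .io import Alignment, PositionMap, ReferenceStructure, NUCLEOTIDES
from .pec import EventCount, PECResult
from .scores import PairStateTable, ScoreMatrix, pair_state_table
from .selection import one_directional_nbest

logger = logging.getLogger(__name__)

#: canonical WC/wobble ordered pair types
CANONICAL_TYPES = frozenset(
    {"G:C", "C:G", "A:U", "U:A", "G:U", "U:G"}
)
_WOBBLE = frozenset({"G:U", "U:G"})
_WC = frozenset({"G:C", "C:G", "A:U", "U:A"})
_VALID = set(NUCLEOTIDES)


# ---------------------------------------------------------------------------
# Helix extension
# ---------------------------------------------------------------------------


@dataclass
class ExtendedPair:
    pair: tuple[int, int]
    canonical_fraction: float
    direction: str                 # "outward" | "inward"
    nucleation: tuple[int, int]


@dataclass
class HelixExtensionResult:
    nucleation_pairs: list[tuple[int, int]]
    extended_pairs: list[ExtendedPair]

    def all_pairs(self) -> list[tuple[int, int]]:
        return sorted(set(self.nucleation_pairs)
                      | {e.pair for e in self.extended_pairs})


def canonical_fraction(alignment: Alignment, col_i: int, col_j: int) -> float:
    """Fraction of sequences forming a canonical pair at two columns.

    The denominator counts only sequences ungapped and unambiguous at both
    columns; 0.0 when no sequence qualifies.
    """
    ci = alignment.column(col_i)
    cj = alignment.column(col_j)
    eligible = 0
    canonical = 0
    for a, b in zip(ci, cj):
        if a in _VALID and b in _VALID:
            eligible += 1
            if f"{a}:{b}" in CANONICAL_TYPES:
                canonical += 1
    return canonical / eligible if eligible else 0.0


def helix_extend(
    alignment: Alignment,
    nucleation_pairs: Iterable[tuple[int, int]],
    canonical_fraction_min: float = 0.85,
) -> HelixExtensionResult:
    """Grow helices outward and inward from each nucleation pair.

    From an accepted pair (i, j), the candidates are (i-1, j+1) (outward)
    and (i+1, j-1) (inward); a candidate is accepted iff its canonical
    fraction is >= ``canonical_fraction_min``.  Extension stops in a
    direction at the first failure or at the alignment boundary.  Pairs
    already in the nucleation set are never re-added; when two extensions
    claim the same column with different partners, the higher canonical
    fraction wins.
    """
    nucleation = sorted({(min(p), max(p)) for p in nucleation_pairs})
    nucleation_set = set(nucleation)
    n_cols = alignment.n_columns

    proposals: dict[tuple[int, int], ExtendedPair] = {}
    for nuc in nucleation:
        for direction, (di, dj) in (("outward", (-1, +1)), ("inward", (+1, -1))):
            i, j = nuc
            while True:
                i, j = i + di, j + dj
                if not (1 <= i <= n_cols and 1 <= j <= n_cols and i < j):
                    break
                pair = (i, j)
                if pair in nucleation_set:
                    break  # ran into an existing nucleation pair
                frac = canonical_fraction(alignment, i, j)
                if frac < canonical_fraction_min:
                    break
                prev = proposals.get(pair)
                if prev is None or frac > prev.canonical_fraction:
                    proposals[pair] = ExtendedPair(pair, frac, direction, nuc)

    # resolve column conflicts: a column claimed by two different partners
    accepted: dict[tuple[int, int], ExtendedPair] = {}
    claimed: dict[int, tuple[int, int]] = {}
    for c in nucleation:
        claimed[c[0]] = c
        claimed[c[1]] = c
    for pair, prop in sorted(
        proposals.items(), key=lambda kv: -kv[1].canonical_fraction
    ):
        i, j = pair
        if claimed.get(i, pair) != pair or claimed.get(j, pair) != pair:
            logger.info(
                "extension %s dropped: column already claimed by %s / %s",
                pair, claimed.get(i), claimed.get(j),
            )
            continue
        accepted[pair] = prop
        claimed[i] = pair
        claimed[j] = pair
    extended = sorted(accepted.values(), key=lambda e: e.pair)
    return HelixExtensionResult(nucleation, extended)


# ---------------------------------------------------------------------------
# Purity
# ---------------------------------------------------------------------------


@dataclass
class PurityResult:
    pair: tuple[int, int]
    ranked_types: list[tuple[str, float]]
    purity: float
    gu_plus_purity: float
    accepted_types: list[str]
    gu_plus_accepted_types: list[str]


def _purity_walk(ranked: Sequence[tuple[str, float]], gu_plus: bool
                 ) -> tuple[float, list[str]]:
    accepted: list[str] = []
    score = 0.0

    def exempt(t: str, acc: str) -> bool:
        # wobble pairs neither block nor are blocked by WC canonical types
        return gu_plus and (
            (t in _WOBBLE and acc in _WC) or (t in _WC and acc in _WOBBLE)
        )

    for t, freq in ranked:
        a5, a3 = t.split(":")
        blocked = False
        for acc in accepted:
            if exempt(t, acc):
                continue
            b5, b3 = acc.split(":")
            if a5 == b5 or a3 == b3:
                blocked = True
                break
        if not blocked:
            accepted.append(t)
            score += freq
    return score, accepted


def purity(table: PairStateTable) -> PurityResult:
    """Purity and GU-plus purity from a joint pair-type table.

    Types are ranked by descending frequency (ties lexicographic); the top
    type is always accepted, and each further type is accepted iff both its
    nucleotides are unused among accepted types — it covaries (both symbols
    change) relative to every accepted type.
    """
    freqs = table.pair_type_freqs()
    if not freqs:
        raise ValueError(
            f"pair ({table.col_x},{table.col_y}): no informative sequences"
        )
    ranked = sorted(freqs.items(), key=lambda kv: (-kv[1], kv[0]))
    p, acc = _purity_walk(ranked, gu_plus=False)
    gp, gacc = _purity_walk(ranked, gu_plus=True)
    return PurityResult((table.col_x, table.col_y), ranked, p, gp, acc, gacc)


def purity_from_counts(counts: Mapping[str, float]) -> PurityResult:
    """Purity of a raw pair-type count/frequency mapping (e.g. ``{"A:U": 2}``)."""
    total = float(sum(counts.values()))
    if total <= 0:
        raise ValueError("empty pair-type table")
    ranked = sorted(
        ((t, c / total) for t, c in counts.items() if c > 0),
        key=lambda kv: (-kv[1], kv[0]),
    )
    p, acc = _purity_walk(ranked, gu_plus=False)
    gp, gacc = _purity_walk(ranked, gu_plus=True)
    return PurityResult((0, 0), ranked, p, gp, acc, gacc)


# ---------------------------------------------------------------------------
# Distances and neighbor effects
# ---------------------------------------------------------------------------


def base_center_distance(
    structure: ReferenceStructure, pos_a: int, pos_b: int
) -> Optional[float]:
    """Euclidean distance (Å) between two bases' hydrogen-bond centers."""
    if structure.base_centers is None:
        raise ValueError("reference structure carries no 3-D coordinates")
    ca = structure.base_centers.get(pos_a)
    cb = structure.base_centers.get(pos_b)
    if ca is None or cb is None:
        logger.warning("no coordinates for position %d or %d",
                       pos_a, pos_b)
        return None
    return float(np.linalg.norm(np.asarray(ca) - np.asarray(cb)))


@dataclass
class NeighborEffect:
    pair: tuple[int, int]
    cpe: float
    nbest_ratio: float             # min of the two columns' ratios
    total_events: int
    distance: Optional[float] = None
    h_bonded_class: str = "unknown"
    ref_pair: Optional[tuple[int, int]] = None


def neighbor_effects(
    pec_result: PECResult,
    called_pairs: Iterable[tuple[int, int]],
    structure: Optional[ReferenceStructure] = None,
    position_map: Optional[PositionMap] = None,
    ratio_min: float = 0.85,
    cpe_min: float = 0.25,
    events_min: int = 10,
) -> list[NeighborEffect]:
    """Identify neighbor effects among CPE-scored pairs not already called.

    A pair qualifies when both columns' one-directional N-Best ratios are
    >= ``ratio_min`` (its covariation is significant but non-exclusive),
    its CPE is >= ``cpe_min`` and its total event count >= ``events_min``.
    With a reference structure, each effect is annotated with the Euclidean
    base-center distance and the hydrogen-bond class of the position pair.
    """
    called = {(min(p), max(p)) for p in called_pairs}
    scores = pec_result.cpe_scores
    ratios: dict[int, Optional[float]] = {}
    for c in scores.columns():
        try:
            ratios[c] = one_directional_nbest(scores, c)
        except ValueError:
            ratios[c] = None

    effects: list[NeighborEffect] = []
    for (i, j) in scores.pairs():
        if (i, j) in called:
            continue
        ev = pec_result.event_counts.get((i, j))
        if ev is None:
            continue
        ri, rj = ratios.get(i), ratios.get(j)
        if ri is None or rj is None:
            continue
        if not (ri >= ratio_min and rj >= ratio_min):
            continue
        if ev.cpe is None or ev.cpe < cpe_min or ev.total < events_min:
            continue
        effect = NeighborEffect((i, j), ev.cpe, min(ri, rj), ev.total)
        if position_map is not None:
            effect.ref_pair = position_map.pair_to_positions(i, j)
        if structure is not None and effect.ref_pair is not None:
            klass = structure.classify(*effect.ref_pair)
            if structure.base_centers is not None:
                effect.distance = base_center_distance(
                    structure, *effect.ref_pair
                )
                effect.h_bonded_class = klass if klass else "none"
            else:
                effect.h_bonded_class = klass if klass else "unknown"
        effects.append(effect)
    return effects


# ---------------------------------------------------------------------------
# Evaluation against a reference structure
# ---------------------------------------------------------------------------


@dataclass
class CallEvaluation:
    pair: tuple[int, int]
    ref_pair: Optional[tuple[int, int]]
    status: str                    # "TP" | "FP" | "unmappable"
    pair_class: Optional[str] = None


@dataclass
class EvaluationReport:
    calls: list[CallEvaluation]
    n_true_positive: int
    n_false_positive: int
    n_unmappable: int
    precision_curve: list[tuple[int, float]]   # (N, precision among top N)

    @property
    def precision(self) -> Optional[float]:
        n = self.n_true_positive + self.n_false_positive
        return self.n_true_positive / n if n else None


def evaluate_calls(
    called_pairs: Sequence[tuple[int, int]],
    position_map: PositionMap,
    structure: ReferenceStructure,
) -> EvaluationReport:
    """Label ranked calls TP/FP against the reference structure.

    ``called_pairs`` must be ranked (best first) for the precision-of-top-N
    curve to be meaningful; calls on columns gapped in the reference are
    reported unmappable and excluded from the counts and the curve.
    """
    evaluations: list[CallEvaluation] = []
    tp = fp = unmappable = 0
    curve: list[tuple[int, float]] = []
    for pair in called_pairs:
        ref_pair = position_map.pair_to_positions(*pair)
        if ref_pair is None:
            logger.info("call %s unmappable: reference-gapped column", pair)
            evaluations.append(CallEvaluation(pair, None, "unmappable"))
            unmappable += 1
            continue
        klass = structure.classify(*ref_pair)
        if klass is not None:
            tp += 1
            evaluations.append(CallEvaluation(pair, ref_pair, "TP", klass))
        else:
            fp += 1
            evaluations.append(CallEvaluation(pair, ref_pair, "FP"))
        curve.append((tp + fp, tp / (tp + fp)))
    return EvaluationReport(evaluations, tp, fp, unmappable, curve)
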