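"""Phylogenetic Event Counting (PEC) for column-pair covariation.

The method maps the two nucleotides of each sequence at a column pair onto
the leaves of a (possibly multifurcating) phylogeny, assigns each internal
node the pair type occurring most frequently among the leaves of its
subtree (a majority variant of Fitch parsimony suited to non-binary
taxonomy trees), and then counts substitution events between each internal
node and its children.  An event where both positions changed is *positive*
(compensatory); where exactly one changed, *negative*.  To avoid bias from
repeated sampling of a lineage, each distinct changed child pair type is
counted only once per internal node.  The covariation percentage of events
(CPE) is positive / (positive + negative).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .io import Alignment, Phylogeny, NUCLEOTIDES
from .scores import ScoreMatrix

logger = logging.getLogger(__name__)

_VALID = set(NUCLEOTIDES)

PairType = str  # ordered "X:Y" string, e.g. "A:U"


@dataclass
class PairStateAssignment:
    """Leaf pair states and majority ("equality set") ancestral assignments.

    ``leaf_states`` holds the ordered pair type of every informative leaf
    (unambiguous nucleotides at both columns); gapped/ambiguous leaves are
    absent.  ``node_states`` assigns each internal node whose subtree holds
    at least one informative leaf the most frequent pair type among those
    leaves, ties broken lexicographically (A < C < G < U).
    """

    col_x: int
    col_y: int
    leaf_states: dict[int, PairType]
    node_states: dict[int, PairType]
    n_informative: int


@dataclass
class EventCount:
    """Positive / negative phylogenetic event tallies for one column pair."""

    positive: int = 0
    negative: int = 0

    @property
    def total(self) -> int:
        return self.positive + self.negative

    @property
    def cpe(self) -> Optional[float]:
        if self.total == 0:
            return None
        return self.positive / self.total


def assign_ancestral_pairs(
    phylogeny: Phylogeny, alignment: Alignment, col_x: int, col_y: int
) -> PairStateAssignment:
    """Majority-parsimony ancestral pair states for one column pair.

    Raises ``ValueError`` when fewer than 2 leaves carry unambiguous,
    ungapped states at both columns.
    """
    cx = alignment.column(col_x)
    cy = alignment.column(col_y)
    idx = {sid: k for k, sid in enumerate(alignment.sequence_ids)}

    leaf_states: dict[int, PairType] = {}
    for leaf, sid in phylogeny.leaf_to_sequence.items():
        k = idx[sid]
        a, b = cx[k], cy[k]
        if a in _VALID and b in _VALID:
            leaf_states[leaf] = f"{a}:{b}"
    if len(leaf_states) < 2:
        raise ValueError(
            f"pair ({col_x},{col_y}): fewer than 2 informative leaves"
        )

    # bottom-up aggregation of subtree leaf pair-type counters
    subtree_counts: dict[int, Counter] = {}
    node_states: dict[int, PairType] = {}
    for node in phylogeny.postorder():
        kids = phylogeny.children[node]
        if not kids:
            c = Counter()
            if node in leaf_states:
                c[leaf_states[node]] = 1
            subtree_counts[node] = c
        else:
            c = Counter()
            for k in kids:
                c.update(subtree_counts[k])
            subtree_counts[node] = c
            if c:
                # majority pair type; ties broken lexicographically
                node_states[node] = min(
                    c, key=lambda t: (-c[t], t)
                )
    return PairStateAssignment(col_x, col_y, leaf_states, node_states,
                               len(leaf_states))


def classify_event(parent: PairType, child: PairType) -> Optional[str]:
    """'positive' if both symbols differ, 'negative' if exactly one, else None."""
    pa, pb = parent.split(":")
    ca, cb = child.split(":")
    changed = (pa != ca) + (pb != cb)
    if changed == 2:
        return "positive"
    if changed == 1:
        return "negative"
    return None


def count_events(assignment: PairStateAssignment, phylogeny: Phylogeny) -> EventCount:
    """De-duplicated event counts over all internal nodes.

    At each internal node with assigned pair type P, the *distinct* child
    pair types differing from P each contribute exactly one event
    (positive or negative), regardless of how many children carry them.
    Children lacking informative data are skipped.
    """
    events = EventCount()
    for node, parent_type in assignment.node_states.items():
        seen: set[PairType] = set()
        for child in phylogeny.children[node]:
            if phylogeny.children[child]:
                child_type = assignment.node_states.get(child)
            else:
                child_type = assignment.leaf_states.get(child)
            if child_type is None or child_type == parent_type:
                continue
            seen.add(child_type)
        for child_type in seen:
            kind = classify_event(parent_type, child_type)
            if kind == "positive":
                events.positive += 1
            elif kind == "negative":
                events.negative += 1
    return events


def cpe(events: EventCount) -> Optional[float]:
    """Covariation percentage of events: positive / total, None when total=0."""
    return events.cpe


def pec_pair(
    phylogeny: Phylogeny, alignment: Alignment, col_x: int, col_y: int
) -> EventCount:
    """Events for one column pair (assignment + counting in one call)."""
    assignment = assign_ancestral_pairs(phylogeny, alignment, col_x, col_y)
    return count_events(assignment, phylogeny)


@dataclass
class PECResult:
    """CPE scores plus per-pair event counts from a PEC scan.

    ``excluded`` flags pairs whose total event count fell below the
    requested minimum; they are retained for inspection but carry no CPE
    entry in ``cpe_scores``.
    """

    cpe_scores: ScoreMatrix
    event_counts: dict[tuple[int, int], EventCount]
    excluded: dict[tuple[int, int], str] = field(default_factory=dict)

    def to_records(self, position_map=None) -> list[dict]:
        rows = []
        for (i, j) in sorted(self.event_counts):
            ev = self.event_counts[(i, j)]
            rec = {
                "col_i": i, "col_j": j,
                "positive_events": ev.positive,
                "negative_events": ev.negative,
                "total_events": ev.total,
                "cpe": ev.cpe,
                "excluded_flag": (i, j) in self.excluded,
            }
            if position_map is not None:
                rec["ref_pos_i"] = position_map.to_position(i)
                rec["ref_pos_j"] = position_map.to_position(j)
            rows.append(rec)
        return rows


def pec_scan(
    alignment: Alignment,
    phylogeny: Phylogeny,
    candidate_pairs: Iterable[tuple[int, int]],
    min_total_events: Optional[int] = None,
) -> PECResult:
    """Run PEC over candidate pairs, optionally flagging low-event pairs.

    Pairs with fewer than ``min_total_events`` total events (or with no
    events at all, where CPE is undefined) are excluded from the CPE score
    matrix but kept in ``event_counts`` with a flag.
    """
    cpe_sm = ScoreMatrix("CPE")
    counts: dict[tuple[int, int], EventCount] = {}
    excluded: dict[tuple[int, int], str] = {}
    for i, j in candidate_pairs:
        key = (min(i, j), max(i, j))
        try:
            ev = pec_pair(phylogeny, alignment, *key)
        except ValueError as exc:
            logger.info("pair %s skipped: %s", key, exc)
            excluded[key] = "uninformative"
            continue
        counts[key] = ev
        if ev.total == 0:
            excluded[key] = "no_events"
        elif min_total_events is not None and ev.total < min_total_events:
            excluded[key] = "below_min_total_events"
        else:
            cpe_sm.set(i, j, ev.cpe)
    return PECResult(cpe_sm, counts, excluded)
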