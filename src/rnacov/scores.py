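"""Frequency-based column statistics: conservation entropy, MIxy, MIp, OMES.

Conventions
-----------
All logarithms are base 2, so entropies and mutual information are in bits.
Gaps count as a state for the conservation entropy (a column that is half
gapped is informative about deletion), but a sequence contributes to a pair
statistic (MIxy, OMES, pair tables) only when it carries an unambiguous
nucleotide at *both* columns: base-pair covariation is defined on
nucleotides.  IUPAC ambiguity codes never count as matches or mismatches;
they simply reduce the number of contributing sequences.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .io import Alignment, GAP, NUCLEOTIDES

logger = logging.getLogger(__name__)

_NT_INDEX = {n: i for i, n in enumerate(NUCLEOTIDES)}


@dataclass
class ColumnProfile:
    """Nucleotide and gap frequencies at one alignment column."""

    freqs: dict[str, float]       # Pi over A,C,G,U
    gap_freq: float               # P_delta
    ambiguous_freq: float
    entropy: float                # bits; low = conserved

    @property
    def conservation(self) -> float:
        """Alias: the entropy used as a conservation score (low = conserved)."""
        return self.entropy

    def inverted_conservation(self) -> float:
        """2 - H, for users expecting high = conserved."""
        return 2.0 - self.entropy


def column_profile(alignment: Alignment, column: int) -> ColumnProfile:
    """Shannon entropy over {A,C,G,U,gap} at a 1-based column.

    Ambiguity codes are excluded from both the numerator and the
    denominator.  An empty effective column yields entropy 0 with a warning.
    """
    chars = alignment.column(column)
    counts = Counter(chars.tolist())
    n_amb = sum(v for k, v in counts.items() if k not in _NT_INDEX and k != GAP)
    n_total = len(chars)
    n_eff = n_total - n_amb
    if n_eff == 0:
        logger.warning("column %d has no unambiguous characters", column)
        return ColumnProfile({n: 0.0 for n in NUCLEOTIDES}, 0.0,
                             1.0 if n_total else 0.0, 0.0)
    freqs = {n: counts.get(n, 0) / n_eff for n in NUCLEOTIDES}
    gap_freq = counts.get(GAP, 0) / n_eff
    entropy = 0.0
    for p in (*freqs.values(), gap_freq):
        if p > 0:
            entropy -= p * math.log2(p)
    return ColumnProfile(freqs, gap_freq, n_amb / n_total if n_total else 0.0,
                         entropy)


def entropy_vector(alignment: Alignment) -> np.ndarray:
    """Conservation entropy for every column, 0-indexed array."""
    return np.array(
        [column_profile(alignment, c).entropy
         for c in range(1, alignment.n_columns + 1)]
    )


# ---------------------------------------------------------------------------
# Pair state tables
# ---------------------------------------------------------------------------


@dataclass
class PairStateTable:
    """Joint nucleotide counts for one ordered column pair (x, y).

    ``counts[i, j]`` is the number of sequences with nucleotide ``i`` at
    column x and ``j`` at column y (A,C,G,U indexing); only sequences
    unambiguous and ungapped at both columns contribute.
    """

    col_x: int
    col_y: int
    counts: np.ndarray            # (4, 4) int
    n_effective: int

    @property
    def joint_freqs(self) -> np.ndarray:
        if self.n_effective == 0:
            return np.zeros((4, 4))
        return self.counts / self.n_effective

    @property
    def marginal_x(self) -> np.ndarray:
        return self.joint_freqs.sum(axis=1)

    @property
    def marginal_y(self) -> np.ndarray:
        return self.joint_freqs.sum(axis=0)

    def pair_type_freqs(self) -> dict[str, float]:
        """Ordered pair-type frequencies, e.g. {"A:U": 0.5, ...}, nonzero only."""
        out: dict[str, float] = {}
        jf = self.joint_freqs
        for i, a in enumerate(NUCLEOTIDES):
            for j, b in enumerate(NUCLEOTIDES):
                if jf[i, j] > 0:
                    out[f"{a}:{b}"] = float(jf[i, j])
        return out


def pair_state_table(alignment: Alignment, col_x: int, col_y: int) -> PairStateTable:
    if col_x == col_y:
        raise ValueError("col_x and col_y must differ")
    cx = alignment.column(col_x)
    cy = alignment.column(col_y)
    counts = np.zeros((4, 4), dtype=int)
    n_eff = 0
    for a, b in zip(cx, cy):
        ia = _NT_INDEX.get(a)
        ib = _NT_INDEX.get(b)
        if ia is None or ib is None:
            continue
        counts[ia, ib] += 1
        n_eff += 1
    return PairStateTable(col_x, col_y, counts, n_eff)


# ---------------------------------------------------------------------------
# Score matrix container
# ---------------------------------------------------------------------------


class ScoreMatrix:
    """Sparse symmetric map from unordered column pairs to a named score."""

    def __init__(self, method: str,
                 entries: Optional[dict[tuple[int, int], float]] = None):
        self.method = method
        self._entries: dict[tuple[int, int], float] = {}
        if entries:
            for (i, j), s in entries.items():
                self.set(i, j, s)

    @staticmethod
    def _key(i: int, j: int) -> tuple[int, int]:
        if i == j:
            raise ValueError("self-pairs are not allowed in a ScoreMatrix")
        return (i, j) if i < j else (j, i)

    def set(self, i: int, j: int, score: float) -> None:
        self._entries[self._key(i, j)] = float(score)

    def get(self, i: int, j: int, default: float = math.nan) -> float:
        return self._entries.get(self._key(i, j), default)

    def __contains__(self, pair: tuple[int, int]) -> bool:
        return self._key(*pair) in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def items(self):
        return self._entries.items()

    def pairs(self) -> list[tuple[int, int]]:
        return sorted(self._entries)

    def columns(self) -> set[int]:
        cols: set[int] = set()
        for i, j in self._entries:
            cols.add(i)
            cols.add(j)
        return cols

    def partners(self, column: int) -> dict[int, float]:
        """All scored partners of ``column`` with their scores."""
        out: dict[int, float] = {}
        for (i, j), s in self._entries.items():
            if i == column:
                out[j] = s
            elif j == column:
                out[i] = s
        return out

    def ranked_partners(self, column: int) -> list[tuple[int, float]]:
        """Partners sorted by descending score, ties by ascending column."""
        return sorted(self.partners(column).items(),
                      key=lambda kv: (-kv[1], kv[0]))

    def to_records(self, position_map=None) -> list[dict]:
        rows = []
        for (i, j) in self.pairs():
            rec = {"col_i": i, "col_j": j,
                   "method": self.method, "score": self._entries[(i, j)]}
            if position_map is not None:
                rec["ref_pos_i"] = position_map.to_position(i)
                rec["ref_pos_j"] = position_map.to_position(j)
            rows.append(rec)
        return rows


# ---------------------------------------------------------------------------
# Mutual information and OMES
# ---------------------------------------------------------------------------


def mixy(table: PairStateTable) -> float:
    """Mutual information (bits) between two columns from their joint table.

    MI = sum over pair types of Pr(M,N) * log2( Pr(M,N) / (Pr(M) Pr(N)) );
    zero-probability terms contribute nothing.  Requires >= 2 contributing
    sequences.
    """
    if table.n_effective < 2:
        raise ValueError(
            f"pair ({table.col_x},{table.col_y}): fewer than 2 informative sequences"
        )
    jf = table.joint_freqs
    px = table.marginal_x
    py = table.marginal_y
    mi = 0.0
    for i in range(4):
        for j in range(4):
            p = jf[i, j]
            if p > 0:
                mi += p * math.log2(p / (px[i] * py[j]))
    return max(mi, 0.0)


def omes(table: PairStateTable) -> float:
    """Observed-minus-expected-squared statistic over all 16 dinucleotide cells.

    OMES = sum_cells (N0 - Ne)^2 / Nt with Ne the product of marginal counts
    over Nt; independence gives 0.
    """
    if table.n_effective < 2:
        raise ValueError(
            f"pair ({table.col_x},{table.col_y}): fewer than 2 informative sequences"
        )
    nt = table.n_effective
    row = table.counts.sum(axis=1).astype(float)
    col = table.counts.sum(axis=0).astype(float)
    expected = np.outer(row, col) / nt
    return float(((table.counts - expected) ** 2).sum() / nt)


def mixy_matrix(alignment: Alignment,
                candidate_pairs: Iterable[tuple[int, int]]) -> ScoreMatrix:
    """MIxy for every candidate column pair; uninformative pairs are skipped."""
    sm = ScoreMatrix("MIxy")
    for i, j in candidate_pairs:
        table = pair_state_table(alignment, i, j)
        if table.n_effective < 2:
            logger.info("pair (%d,%d) skipped: <2 informative sequences", i, j)
            continue
        sm.set(i, j, mixy(table))
    return sm


def mip(scores: ScoreMatrix) -> ScoreMatrix:
    """Average-product-corrected mutual information over the scored pair set.

    MIp(a,b) = MIxy(a,b) - mean_MI(a,.) * mean_MI(.,b) / overall_mean_MI,
    with all means taken over the pairs actually scored.  A uniform input
    matrix yields exactly zero everywhere; an all-zero input yields zeros
    with a warning (the correction is then undefined).
    """
    pairs = scores.pairs()
    if not pairs:
        raise ValueError("empty MIxy matrix")
    col_means = {c: np.mean(list(scores.partners(c).values()))
                 for c in scores.columns()}
    overall = float(np.mean([s for _, s in scores.items()]))
    mip_sm = ScoreMatrix("MIp")
    if overall == 0.0:
        logger.warning("overall mean MI is 0; all MIp set to 0")
        for i, j in pairs:
            mip_sm.set(i, j, 0.0)
    else:
        for i, j in pairs:
            apc = col_means[i] * col_means[j] / overall
            mip_sm.set(i, j, scores.get(i, j) - apc)
    return mip_sm


def zscores(scores: ScoreMatrix) -> ScoreMatrix:
    """Standardize a score matrix over its scored pairs (mean 0, sd 1).

    Raises ``ValueError`` when the scores are constant (sd = 0).
    """
    values = np.array([s for _, s in scores.items()])
    sd = float(values.std())
    if sd == 0.0:
        raise ValueError(f"{scores.method} values are constant; "
                         "Z-scores undefined")
    mean = float(values.mean())
    z_sm = ScoreMatrix(f"{scores.method}_Z")
    for (i, j), s in scores.items():
        z_sm.set(i, j, (s - mean) / sd)
    return z_sm


def omes_matrix(alignment: Alignment,
                candidate_pairs: Iterable[tuple[int, int]]) -> ScoreMatrix:
    sm = ScoreMatrix("OMES")
    for i, j in candidate_pairs:
        table = pair_state_table(alignment, i, j)
        if table.n_effective < 2:
            logger.info("pair (%d,%d) skipped: <2 informative sequences", i, j)
            continue
        sm.set(i, j, omes(table))
    return sm


def n_unordered_pairs(n_columns: int) -> int:
    """Number of unordered column pairs in an n-column alignment."""
    return n_columns * (n_columns - 1) // 2
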