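"""Synthetic phylogenies and alignments with known covariation structure.

The generator emulates the salient features of curated rRNA alignments on
a taxonomy-style tree: a rooted multifurcating phylogeny; *planted pairs*
of columns that substitute jointly between canonical partner types
(compensatory substitutions, the signal PEC and MI are built to detect);
*helix blocks* — stacks of adjacent antiparallel pairs in which only one
pair varies while the flanking pairs are invariant canonical (the regime
helix extension addresses); independently evolving unpaired columns;
perfectly conserved columns; and all-gap columns.

Substitutions are applied per edge as Bernoulli events at a fixed per-edge
probability rather than via a continuous-time model: PEC counts discrete
events, so a discrete generator makes truth comparisons exact.  Every
substitution is recorded in the emitted truth table, which is sufficient
to score precision/recall for every selection stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .io import Alignment, Phylogeny

#: canonical pair types a planted pair cycles through
_CANONICAL_CYCLE = ("G:C", "A:U", "U:A", "C:G")
_WOBBLE = ("G:U", "U:G")
_BASES = ("A", "C", "G", "U")


@dataclass
class HelixBlock:
    """A stack of nested pairs; only ``varying_pair`` substitutes."""

    pairs: list[tuple[int, int]]
    varying_pair: tuple[int, int]

    @property
    def invariant_pairs(self) -> list[tuple[int, int]]:
        return [p for p in self.pairs if p != self.varying_pair]


@dataclass
class SynthSpec:
    """Parameters of one synthetic dataset.

    Defaults describe a mid-sized comparative dataset: 200 sequences on a
    random multifurcating tree, 120 alignment columns, 8 standalone
    compensatory pairs plus 4 helix blocks of 3 pairs whose middle pair
    varies (20 planted-pair columns in total, the remaining truth pairs
    invariant), a per-edge substitution probability of 0.08 for both
    compensatory and unpaired columns, 12 conserved and 6 all-gap columns.
    """

    n_leaves: int = 200
    n_columns: int = 120
    tree_shape: str = "random"      # random | balanced | star
    n_planted_pairs: int = 8        # standalone compensatory pairs
    n_helix_blocks: int = 4
    helix_block_length: int = 3     # pairs per block; middle pair varies
    compensatory_rate: float = 0.08  # per-edge substitution probability
    unpaired_substitution_rate: float = 0.08
    conserved_column_fraction: float = 0.10
    gap_column_fraction: float = 0.05
    gu_visits: bool = False         # allow wobble states in planted pairs
    seed: int = 0


@dataclass
class Truth:
    """Ground truth emitted next to a simulated dataset."""

    planted_pairs: list[tuple[int, int]]       # all compensatory (varying) pairs
    helix_blocks: list[HelixBlock]
    column_roles: dict[int, str]               # paired|helix|unpaired|conserved|gap
    #: per varying pair: (child_node, from_type, to_type) for each substitution
    substitutions: dict[tuple[int, int], list[tuple[int, str, str]]]

    def all_true_pairs(self) -> list[tuple[int, int]]:
        pairs = set(self.planted_pairs)
        for block in self.helix_blocks:
            pairs.update(block.pairs)
        return sorted(pairs)


def _random_multifurcating(rng: np.random.Generator, n_leaves: int) -> Phylogeny:
    phylo = Phylogeny()
    root = phylo.add_node(None)
    leaves = [phylo.add_node(root) for _ in range(min(n_leaves, 3))]
    # attach remaining leaves under random internal or leaf nodes, sometimes
    # splitting a leaf into an internal node to deepen the tree
    while len(leaves) < n_leaves:
        remaining = n_leaves - len(leaves)
        # splitting a leaf into k children nets k-1 new leaves
        can_split = leaves and remaining >= 1
        if can_split and rng.random() < 0.5:
            k_max = min(4, remaining + 1)
            if k_max >= 2:
                target = leaves.pop(int(rng.integers(len(leaves))))
                k = int(rng.integers(2, k_max + 1))
                for _ in range(k):
                    leaves.append(phylo.add_node(target))
                continue
        internal = [n for n in phylo.parent if phylo.children[n]]
        target = internal[int(rng.integers(len(internal)))]
        leaves.append(phylo.add_node(target))
    return phylo


def _balanced(n_leaves: int) -> Phylogeny:
    phylo = Phylogeny()

    def build(parent: Optional[int], n: int) -> None:
        node = phylo.add_node(parent)
        if n == 1:
            return
        left = n // 2
        build(node, left)
        build(node, n - left)

    build(None, n_leaves)
    return phylo


def _star(n_leaves: int) -> Phylogeny:
    phylo = Phylogeny()
    root = phylo.add_node(None)
    for _ in range(n_leaves):
        phylo.add_node(root)
    return phylo


def make_tree(spec: SynthSpec, rng: np.random.Generator) -> Phylogeny:
    if spec.tree_shape == "random":
        return _random_multifurcating(rng, spec.n_leaves)
    if spec.tree_shape == "balanced":
        return _balanced(spec.n_leaves)
    if spec.tree_shape == "star":
        return _star(spec.n_leaves)
    raise ValueError(f"unknown tree shape: {spec.tree_shape}")


def _layout_columns(spec: SynthSpec, rng: np.random.Generator
                    ) -> tuple[list[tuple[int, int]], list[HelixBlock],
                               dict[int, str]]:
    """Assign roles to columns: helix blocks first, then standalone pairs,
    then conserved / gap / unpaired among the remainder."""
    n = spec.n_columns
    block_span = 2 * spec.helix_block_length
    needed = (spec.n_helix_blocks * (block_span + 1)  # +1 spacer per block
              + 2 * spec.n_planted_pairs)
    if needed > n:
        raise ValueError(
            f"spec infeasible: {needed} paired/spacer columns exceed "
            f"{n} columns"
        )
    roles: dict[int, str] = {}
    blocks: list[HelixBlock] = []
    col = 1
    for _ in range(spec.n_helix_blocks):
        start = col
        L = spec.helix_block_length
        end = start + 2 * L - 1
        pairs = [(start + k, end - k) for k in range(L)]
        varying = pairs[L // 2]
        blocks.append(HelixBlock(pairs, varying))
        for c in range(start, end + 1):
            roles[c] = "helix"
        col = end + 2  # leave a spacer column between blocks
        if col <= n:
            roles[col - 1] = "unpaired"

    free = [c for c in range(1, n + 1) if c not in roles]
    free = list(rng.permutation(free))
    planted: list[tuple[int, int]] = []
    for _ in range(spec.n_planted_pairs):
        a, b = int(free.pop()), int(free.pop())
        planted.append((min(a, b), max(a, b)))
        roles[planted[-1][0]] = roles[planted[-1][1]] = "paired"

    n_gap = int(round(spec.gap_column_fraction * n))
    n_conserved = int(round(spec.conserved_column_fraction * n))
    for _ in range(min(n_gap, len(free))):
        roles[int(free.pop())] = "gap"
    for _ in range(min(n_conserved, len(free))):
        roles[int(free.pop())] = "conserved"
    for c in free:
        roles[int(c)] = "unpaired"
    return sorted(planted), blocks, roles


def simulate(spec: SynthSpec) -> tuple[Alignment, Phylogeny, Truth]:
    """Evolve sequences root→leaves along the tree; byte-deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    phylo = make_tree(spec, rng)
    planted, blocks, roles = _layout_columns(spec, rng)

    varying_pairs = sorted(set(planted) | {b.varying_pair for b in blocks})
    invariant_pairs = [p for b in blocks for p in b.invariant_pairs]
    unpaired_cols = [c for c, r in roles.items() if r == "unpaired"]
    conserved_cols = [c for c, r in roles.items() if r == "conserved"]
    gap_cols = [c for c, r in roles.items() if r == "gap"]

    pair_states = _CANONICAL_CYCLE + (_WOBBLE if spec.gu_visits else ())

    # root state
    root_pair_state: dict[tuple[int, int], str] = {}
    for p in varying_pairs + invariant_pairs:
        root_pair_state[p] = pair_states[int(rng.integers(len(pair_states)))]
    root_base: dict[int, str] = {}
    for c in unpaired_cols + conserved_cols:
        root_base[c] = _BASES[int(rng.integers(4))]

    substitutions: dict[tuple[int, int], list[tuple[int, str, str]]] = {
        p: [] for p in varying_pairs
    }
    leaf_rows: dict[int, str] = {}

    def render(pair_state: dict, base_state: dict) -> str:
        chars = ["-"] * spec.n_columns
        for (i, j), t in pair_state.items():
            a, b = t.split(":")
            chars[i - 1], chars[j - 1] = a, b
        for c, b in base_state.items():
            chars[c - 1] = b
        return "".join(chars)

    # depth-first evolution; children visited in insertion order for
    # determinism
    stack: list[tuple[int, dict, dict]] = [
        (phylo.root, root_pair_state, root_base)
    ]
    while stack:
        node, pstate, bstate = stack.pop()
        kids = phylo.children[node]
        if not kids:
            leaf_rows[node] = render(pstate, bstate)
            continue
        for child in reversed(kids):
            cp = dict(pstate)
            cb = dict(bstate)
            for p in varying_pairs:
                if rng.random() < spec.compensatory_rate:
                    current = cp[p]
                    options = [t for t in pair_states if t != current]
                    new = options[int(rng.integers(len(options)))]
                    cp[p] = new
                    substitutions[p].append((child, current, new))
            for c in unpaired_cols:
                if rng.random() < spec.unpaired_substitution_rate:
                    options = [b for b in _BASES if b != cb[c]]
                    cb[c] = options[int(rng.integers(3))]
            stack.append((child, cp, cb))

    leaves = sorted(leaf_rows)
    width = len(str(len(leaves)))
    ids = [f"seq{str(k + 1).zfill(width)}" for k in range(len(leaves))]
    alignment = Alignment(ids, [leaf_rows[l] for l in leaves])
    for sid, leaf in zip(ids, leaves):
        phylo.leaf_to_sequence[leaf] = sid

    truth = Truth(
        planted_pairs=varying_pairs,
        helix_blocks=blocks,
        column_roles=roles,
        substitutions=substitutions,
    )
    return alignment, phylo, truth


# ---------------------------------------------------------------------------
# On-disk outputs
# ---------------------------------------------------------------------------


def write_newick(phylogeny: Phylogeny, path: str | Path) -> None:
    """Serialize a Phylogeny to Newick with sequence ids as leaf labels."""

    def render(node: int) -> str:
        kids = phylogeny.children[node]
        if not kids:
            return phylogeny.leaf_to_sequence.get(node, f"n{node}")
        return "(" + ",".join(render(k) for k in kids) + ")"

    import sys
    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 4 * len(phylogeny.parent) + 100))
    try:
        text = render(phylogeny.root) + ";\n"
    finally:
        sys.setrecursionlimit(old)
    Path(path).write_text(text)


def write_truth(truth: Truth, path: str | Path) -> None:
    """Truth table as TSV: one row per true pair with its role."""
    with open(path, "w") as fh:
        fh.write("col_i\tcol_j\trole\tn_substitutions\n")
        block_pairs = {p for b in truth.helix_blocks for p in b.pairs}
        for (i, j) in truth.all_true_pairs():
            if (i, j) in truth.substitutions:
                role = "varying"
                n_sub = len(truth.substitutions[(i, j)])
            else:
                role = "invariant_helix"
                n_sub = 0
            if (i, j) in block_pairs:
                role += "_in_block"
            fh.write(f"{i}\t{j}\t{role}\t{n_sub}\n")
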