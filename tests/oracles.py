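"""Independent brute-force reference implementations used only by tests.

These re-derive the event-counting, APC-correction and purity rules from
scratch over small instances, with a deliberately different representation
(nested tuples, plain recursion) from the package's engine, so that
agreement is a genuine cross-check rather than a tautology.
"""

from __future__ import annotations

from collections import Counter
from itertools import product


# ---------------------------------------------------------------------------
# Brute-force event counting on nested-tuple trees
# ---------------------------------------------------------------------------
# A tree is either a leaf -- a pair-type string like "A:U" -- or a tuple of
# subtrees (any arity >= 2).


def leaf_types(tree) -> list[str]:
    if isinstance(tree, str):
        return [tree]
    out = []
    for sub in tree:
        out.extend(leaf_types(sub))
    return out


def majority_type(tree) -> str:
    """Most frequent leaf pair type in the subtree, ties lexicographic."""
    counts = Counter(leaf_types(tree))
    best = max(counts.values())
    return min(t for t, c in counts.items() if c == best)


def brute_force_events(tree) -> tuple[int, int]:
    """(positive, negative) event counts by direct recursive application
    of the rules: majority assignment, per-node distinct-type
    de-duplication, both-changed = positive, one-changed = negative."""
    if isinstance(tree, str):
        return (0, 0)
    parent = majority_type(tree)
    pos = neg = 0
    distinct = set()
    for sub in tree:
        child = sub if isinstance(sub, str) else majority_type(sub)
        if child != parent:
            distinct.add(child)
    for child in distinct:
        pa, pb = parent.split(":")
        ca, cb = child.split(":")
        n_changed = (pa != ca) + (pb != cb)
        if n_changed == 2:
            pos += 1
        else:
            neg += 1
    for sub in tree:
        p, n = brute_force_events(sub)
        pos += p
        neg += n
    return pos, neg


def enumerate_topologies(leaves: tuple):
    """All rooted multifurcating tree shapes over an ordered leaf tuple.

    Every internal node partitions its leaf set into >= 2 blocks; each
    multi-leaf block is recursively any tree shape over that block.
    """
    if len(leaves) == 1:
        yield leaves[0]
        return
    for partition in _set_partitions(list(leaves)):
        if len(partition) < 2:
            continue
        block_trees = [list(enumerate_topologies(tuple(b))) for b in partition]
        for combo in product(*block_trees):
            yield tuple(combo)


def _set_partitions(items):
    if len(items) == 1:
        yield [items]
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def relabel(topology, states: dict):
    """Replace leaf labels in a topology with their pair-type states."""
    if not isinstance(topology, tuple):
        return states[topology]
    return tuple(relabel(sub, states) for sub in topology)


# ---------------------------------------------------------------------------
# Brute-force APC correction
# ---------------------------------------------------------------------------


def brute_force_apc(mi: dict[tuple[int, int], float]
                    ) -> dict[tuple[int, int], float]:
    """MIp by literal application of the average-product correction."""
    cols = sorted({c for pair in mi for c in pair})
    mean_col = {}
    for c in cols:
        vals = [v for (i, j), v in mi.items() if c in (i, j)]
        mean_col[c] = sum(vals) / len(vals)
    overall = sum(mi.values()) / len(mi)
    return {
        (i, j): v - mean_col[i] * mean_col[j] / overall
        for (i, j), v in mi.items()
    }


# ---------------------------------------------------------------------------
# Brute-force purity walk
# ---------------------------------------------------------------------------


def brute_force_purity(freqs: dict[str, float]) -> float:
    """Greedy ranked walk accepting a type iff both symbols are fresh."""
    ranked = sorted(freqs.items(), key=lambda kv: (-kv[1], kv[0]))
    used5: set[str] = set()
    used3: set[str] = set()
    total = 0.0
    for t, f in ranked:
        a, b = t.split(":")
        if a not in used5 and b not in used3:
            used5.add(a)
            used3.add(b)
            total += f
    return total / sum(freqs.values())


# ---------------------------------------------------------------------------
# Brute-force OMES (all-16-cell convention)
# ---------------------------------------------------------------------------


def brute_force_omes(pairs: list[tuple[str, str]]) -> float:
    nt = len(pairs)
    xs = Counter(a for a, _ in pairs)
    ys = Counter(b for _, b in pairs)
    obs = Counter(pairs)
    total = 0.0
    for a in "ACGU":
        for b in "ACGU":
            ne = xs[a] * ys[b] / nt
            total += (obs[(a, b)] - ne) ** 2
    return total / nt
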