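"""Readers, writers and coordinate plumbing for RNA covariation analysis.

All user-facing coordinates are 1-based and inclusive, matching BPSEQ/CT
conventions and the rRNA reference numbering used in comparative studies.
Internally, alignment columns are stored 0-based in a numpy character grid.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: unambiguous nucleotide states; everything else (N, R, Y, ...) is ambiguous
NUCLEOTIDES = ("A", "C", "G", "U")
GAP = "-"


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------


class Alignment:
    """An RNA multiple sequence alignment.

    Rows are equal-length uppercase strings over ``A,C,G,U,-`` plus IUPAC
    ambiguity codes, which are preserved as given.  ``T`` is normalized to
    ``U`` and ``.`` to ``-`` on construction.
    """

    def __init__(self, sequence_ids: Iterable[str], rows: Iterable[str]):
        self.sequence_ids = list(sequence_ids)
        rows = [self._normalize(r) for r in rows]
        if len(self.sequence_ids) != len(rows):
            raise ValueError("sequence_ids and rows length mismatch")
        if len(rows) < 2:
            raise ValueError("an alignment needs at least 2 sequences")
        if len(set(self.sequence_ids)) != len(self.sequence_ids):
            raise ValueError("duplicate sequence identifiers")
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            ragged = [
                sid for sid, r in zip(self.sequence_ids, rows)
                if len(r) != len(rows[0])
            ]
            raise FormatError(f"ragged alignment rows for records: {ragged}")
        self.rows = rows
        # (n_sequences, n_columns) byte grid for fast column slicing
        self._grid = np.array([list(r) for r in rows], dtype="U1")
        self._index = {sid: i for i, sid in enumerate(self.sequence_ids)}

    @staticmethod
    def _normalize(row: str) -> str:
        return row.upper().replace("T", "U").replace(".", "-")

    @property
    def n_sequences(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return self._grid.shape[1]

    def row(self, sequence_id: str) -> str:
        return self.rows[self._index[sequence_id]]

    def column(self, column: int) -> np.ndarray:
        """Return the 1-based column as an array of single characters."""
        if not 1 <= column <= self.n_columns:
            raise IndexError(f"column {column} out of range 1..{self.n_columns}")
        return self._grid[:, column - 1]

    def columns_for(self, sequence_ids: Iterable[str], column: int) -> np.ndarray:
        idx = [self._index[s] for s in sequence_ids]
        return self._grid[idx, column - 1]

    def __repr__(self) -> str:  # pragma: no cover
        return f"Alignment({self.n_sequences} sequences x {self.n_columns} columns)"


def read_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA file, normalizing T→U and '.'→'-'.

    Raises :class:`FormatError` on ragged rows or an empty file.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    aln = Alignment([r.id for r in records], [str(r.seq) for r in records])
    logger.info(
        "read alignment %s: %d sequences, %d columns",
        path, aln.n_sequences, aln.n_columns,
    )
    return aln


def write_alignment(alignment: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, row in zip(alignment.sequence_ids, alignment.rows):
            fh.write(f">{sid}\n{row}\n")


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------


class Phylogeny:
    """A rooted phylogeny; internal nodes may have any number of children.

    Nodes are integer ids; ``children[node]`` lists direct children in
    insertion order, ``parent[node]`` is ``None`` for the root only.
    ``leaf_to_sequence`` attaches alignment sequence ids to leaves; several
    leaves may be attached beneath one taxon when sequences share a taxon.
    """

    def __init__(self):
        self.parent: dict[int, Optional[int]] = {}
        self.children: dict[int, list[int]] = {}
        self.leaf_to_sequence: dict[int, str] = {}
        self._next_id = 0

    def add_node(self, parent: Optional[int] = None) -> int:
        node = self._next_id
        self._next_id += 1
        self.parent[node] = parent
        self.children[node] = []
        if parent is not None:
            self.children[parent].append(node)
        return node

    @property
    def root(self) -> int:
        roots = [n for n, p in self.parent.items() if p is None]
        if len(roots) != 1:
            raise FormatError(f"tree has {len(roots)} roots; exactly one required")
        return roots[0]

    @property
    def nodes(self) -> list[int]:
        return list(self.parent)

    def leaves(self) -> list[int]:
        return [n for n in self.parent if not self.children[n]]

    def internal_nodes(self) -> list[int]:
        return [n for n in self.parent if self.children[n]]

    def postorder(self) -> list[int]:
        """Children before parents, iterative (taxonomy trees are deep)."""
        order: list[int] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(self.children[node])
        order.reverse()
        return order

    def validate(self) -> None:
        root = self.root  # raises if not exactly one
        seen = set()
        stack = [root]
        while stack:
            node = stack.pop()
            if node in seen:
                raise FormatError("cycle detected in phylogeny")
            seen.add(node)
            stack.extend(self.children[node])
        if len(seen) != len(self.parent):
            raise FormatError("nodes unreachable from root (cycle or forest)")

    def collapse_unary(self) -> None:
        """Collapse single-child chains.

        No substitution event can occur across a unary edge under the
        majority-parsimony rule, so counts are unaffected; traversals shrink.
        """
        changed = True
        while changed:
            changed = False
            for node in list(self.parent):
                kids = self.children.get(node)
                if kids is None or len(kids) != 1:
                    continue
                (child,) = kids
                par = self.parent[node]
                if par is None:
                    # root with one child: make the child the root
                    self.parent[child] = None
                else:
                    i = self.children[par].index(node)
                    self.children[par][i] = child
                    self.parent[child] = par
                del self.parent[node]
                del self.children[node]
                changed = True

    def __repr__(self) -> str:  # pragma: no cover
        return f"Phylogeny({len(self.parent)} nodes, {len(self.leaves())} leaves)"


def _phylogeny_from_dendropy(tree) -> tuple[Phylogeny, dict[int, str]]:
    phylo = Phylogeny()
    node_map: dict[int, int] = {}
    labels: dict[int, str] = {}
    for nd in tree.preorder_node_iter():
        parent = node_map[id(nd.parent_node)] if nd.parent_node is not None else None
        node = phylo.add_node(parent)
        node_map[id(nd)] = node
        label = None
        if nd.taxon is not None:
            label = nd.taxon.label
        elif nd.label:
            label = nd.label
        if label is not None:
            labels[node] = label.replace(" ", "_")
    return phylo, labels


def read_phylogeny(
    path: str | Path,
    format: str = "newick",
    mapping: Optional[str | Path | Mapping[str, str]] = None,
    alignment: Optional[Alignment] = None,
) -> Phylogeny:
    """Read a phylogeny from Newick or an NCBI taxdump directory.

    ``mapping`` links sequence ids to leaf labels / taxon ids (two-column
    TSV path or a dict).  Without a mapping, Newick leaf labels are assumed
    to be sequence ids.  Sequences whose label or taxon is absent from the
    tree are dropped with a warning; when ``alignment`` is given, mapped
    sequences absent from the alignment raise an error.
    """
    seq_to_label: Optional[dict[str, str]] = None
    if mapping is not None:
        if isinstance(mapping, Mapping):
            seq_to_label = dict(mapping)
        else:
            seq_to_label = {}
            with open(mapping) as fh:
                for line in fh:
                    line = line.strip()
                    if not line or line.startswith("#"):
                        continue
                    sid, label = line.split("\t")[:2]
                    seq_to_label[sid] = label

    if format == "newick":
        import dendropy

        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
        phylo, labels = _phylogeny_from_dendropy(tree)
        label_to_node: dict[str, int] = {}
        for node, label in labels.items():
            if not phylo.children[node]:
                label_to_node.setdefault(label, node)
    elif format == "ncbi_taxdump":
        phylo, label_to_node = _read_taxdump(path)
    else:
        raise ValueError(f"unknown phylogeny format: {format}")

    phylo.validate()

    if seq_to_label is None:
        # leaf labels ARE the sequence ids
        seq_to_label = {label: label for label in label_to_node}

    sequence_ids = (
        alignment.sequence_ids if alignment is not None
        else list(seq_to_label)
    )
    missing_nodes = [
        sid for sid in sequence_ids
        if sid in seq_to_label and seq_to_label[sid] not in label_to_node
    ]
    if missing_nodes and isinstance(mapping, (str, Path, Mapping)) and mapping is not None:
        raise FormatError(
            f"mapping refers to tree nodes that do not exist for: {missing_nodes}"
        )
    unmapped = [sid for sid in sequence_ids if sid not in seq_to_label]
    if unmapped:
        warnings.warn(
            f"{len(unmapped)} sequences absent from the tree mapping were "
            f"dropped: {unmapped[:10]}{'...' if len(unmapped) > 10 else ''}"
        )
    for sid in sequence_ids:
        label = seq_to_label.get(sid)
        if label is None:
            continue
        node = label_to_node[label]
        if phylo.children[node]:
            # taxon is internal (taxdump or already a hub of sequence
            # leaves) -- hang the sequence as a new leaf beneath it
            leaf = phylo.add_node(node)
            phylo.leaf_to_sequence[leaf] = sid
        elif node in phylo.leaf_to_sequence:
            # several sequences share one taxon: attach leaves under it
            first = phylo.leaf_to_sequence.pop(node)
            for s in (first, sid):
                leaf = phylo.add_node(node)
                phylo.leaf_to_sequence[leaf] = s
        else:
            phylo.leaf_to_sequence[node] = sid

    phylo.collapse_unary()
    # drop leaves carrying no sequence (tree taxa not in the alignment)
    _prune_unmapped_leaves(phylo)
    phylo.collapse_unary()
    return phylo


def _prune_unmapped_leaves(phylo: Phylogeny) -> None:
    changed = True
    while changed:
        changed = False
        for node in list(phylo.parent):
            if node not in phylo.parent:
                continue
            if not phylo.children[node] and node not in phylo.leaf_to_sequence:
                par = phylo.parent[node]
                if par is None:
                    continue
                phylo.children[par].remove(node)
                del phylo.parent[node]
                del phylo.children[node]
                changed = True


def _read_taxdump(path: str | Path) -> tuple[Phylogeny, dict[str, int]]:
    """Read NCBI nodes.dmp from a taxdump directory (or the file itself)."""
    path = Path(path)
    nodes_file = path / "nodes.dmp" if path.is_dir() else path
    parent_of: dict[str, str] = {}
    with open(nodes_file) as fh:
        for line in fh:
            parts = [p.strip() for p in line.split("|")]
            if len(parts) < 2:
                continue
            taxid, parent_id = parts[0], parts[1]
            parent_of[taxid] = parent_id
    phylo = Phylogeny()
    label_to_node: dict[str, int] = {}

    def ensure(taxid: str) -> int:
        if taxid in label_to_node:
            return label_to_node[taxid]
        parent_id = parent_of.get(taxid)
        if parent_id is None or parent_id == taxid:  # root points to itself
            node = phylo.add_node(None)
        else:
            node = phylo.add_node(ensure(parent_id))
        label_to_node[taxid] = node
        return node

    import sys
    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, len(parent_of) + 100))
    try:
        for taxid in parent_of:
            ensure(taxid)
    finally:
        sys.setrecursionlimit(old_limit)
    return phylo, label_to_node


# ---------------------------------------------------------------------------
# Reference structure
# ---------------------------------------------------------------------------


@dataclass
class ReferenceStructure:
    """Annotated base pairs of a reference molecule, 1-based ungapped coords.

    ``pair_class`` maps each (i, j), i<j, to ``"secondary"`` or ``"tertiary"``.
    ``base_centers`` optionally holds a 3-D coordinate (Å) per position: the
    centroid of the Watson-Crick-edge hydrogen-bonding atoms of that base.
    """

    reference_sequence_id: str
    pairs: set[tuple[int, int]] = field(default_factory=set)
    pair_class: dict[tuple[int, int], str] = field(default_factory=dict)
    base_centers: Optional[dict[int, np.ndarray]] = None
    sequence: Optional[str] = None

    def add_pair(self, i: int, j: int, klass: str) -> None:
        if i == j:
            raise FormatError(f"position {i} paired to itself")
        pair = (min(i, j), max(i, j))
        self.pairs.add(pair)
        self.pair_class[pair] = klass

    def classify(self, i: int, j: int) -> Optional[str]:
        return self.pair_class.get((min(i, j), max(i, j)))


#: atoms whose centroid defines a base's hydrogen-bonding center; the
#: Watson-Crick edge atoms, configurable because the convention is not unique
WC_EDGE_ATOMS: dict[str, tuple[str, ...]] = {
    "A": ("N1", "C2", "N6"),
    "G": ("N1", "N2", "O6"),
    "C": ("N3", "O2", "N4"),
    "U": ("N3", "O2", "O4"),
}


def read_reference_structure(
    structure_path: str | Path,
    reference_sequence_id: str,
    format: Optional[str] = None,
    tertiary_tsv: Optional[str | Path] = None,
    pdb: Optional[str | Path] = None,
    pdb_chain: Optional[str] = None,
    edge_atoms: Mapping[str, tuple[str, ...]] = WC_EDGE_ATOMS,
) -> ReferenceStructure:
    """Read secondary pairs from BPSEQ/CT plus optional tertiary pairs and PDB.

    BPSEQ lines are ``pos base partner`` (partner 0 = unpaired); CT lines are
    ``pos base prev next partner pos``.  Tertiary pairs come from a
    two-column TSV and are tagged ``tertiary``.  When a PDB file is given,
    per-position base centers are computed as the centroid of the
    Watson-Crick edge atoms.
    """
    structure_path = Path(structure_path)
    if format is None:
        format = "ct" if structure_path.suffix.lower() == ".ct" else "bpseq"
    ref = ReferenceStructure(reference_sequence_id=reference_sequence_id)
    partner_of: dict[int, int] = {}
    seq_chars: dict[int, str] = {}
    with open(structure_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if format == "bpseq":
                if len(parts) != 3 or not parts[0].isdigit():
                    continue
                pos, base, partner = int(parts[0]), parts[1], int(parts[2])
            else:  # ct
                if len(parts) < 6 or not parts[0].isdigit():
                    continue
                pos, base, partner = int(parts[0]), parts[1], int(parts[4])
            seq_chars[pos] = base.upper().replace("T", "U")
            if partner == 0:
                continue
            if pos in partner_of and partner_of[pos] != partner:
                raise FormatError(
                    f"position {pos} paired to both {partner_of[pos]} and {partner}"
                )
            partner_of[pos] = partner
    for pos, partner in partner_of.items():
        if partner_of.get(partner, pos) != pos:
            raise FormatError(
                f"inconsistent pairing: {pos}->{partner} but "
                f"{partner}->{partner_of.get(partner)}"
            )
        if pos < partner:
            ref.add_pair(pos, partner, "secondary")
    if seq_chars:
        ref.sequence = "".join(
            seq_chars.get(i, "N") for i in range(1, max(seq_chars) + 1)
        )

    if tertiary_tsv is not None:
        with open(tertiary_tsv) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                i, j = int(parts[0]), int(parts[1])
                klass = parts[2] if len(parts) > 2 else "tertiary"
                pair = (min(i, j), max(i, j))
                if pair not in ref.pairs:  # secondary annotation wins
                    ref.add_pair(i, j, klass)

    if pdb is not None:
        ref.base_centers = _base_centers_from_pdb(
            pdb, chain=pdb_chain, edge_atoms=edge_atoms, reference=ref
        )
    return ref


def _base_centers_from_pdb(
    pdb_path: str | Path,
    chain: Optional[str],
    edge_atoms: Mapping[str, tuple[str, ...]],
    reference: ReferenceStructure,
) -> dict[int, np.ndarray]:
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    model = parser.get_structure("ref", str(pdb_path))[0]
    chains = list(model)
    if chain is not None:
        chains = [c for c in chains if c.id == chain]
        if not chains:
            raise FormatError(f"chain {chain!r} not found in {pdb_path}")
    centers: dict[int, np.ndarray] = {}
    mismatches = []
    for ch in chains:
        for residue in ch:
            resname = residue.get_resname().strip()
            if resname not in WC_EDGE_ATOMS:
                continue
            pos = residue.id[1]
            if reference.sequence and 1 <= pos <= len(reference.sequence):
                expected = reference.sequence[pos - 1]
                if expected in NUCLEOTIDES and expected != resname:
                    mismatches.append((pos, expected, resname))
            coords = [
                residue[a].coord for a in edge_atoms[resname] if a in residue
            ]
            if coords:
                centers[pos] = np.mean(np.asarray(coords, dtype=float), axis=0)
        if centers and chain is None:
            break  # default: first nucleic chain only
    if mismatches and len(mismatches) > 0.1 * max(len(centers), 1):
        raise FormatError(
            f"PDB/reference sequence mismatch at {len(mismatches)} positions "
            f"(first few: {mismatches[:5]}); check chain selection or numbering offset"
        )
    return centers


# ---------------------------------------------------------------------------
# Position map
# ---------------------------------------------------------------------------


@dataclass
class PositionMap:
    """Bijection between alignment columns and ungapped reference positions.

    Columns where the reference row carries a gap map to ``None``.  Both
    directions are 1-based.
    """

    column_to_position: dict[int, Optional[int]]
    position_to_column: dict[int, int]

    def to_position(self, column: int) -> Optional[int]:
        return self.column_to_position.get(column)

    def to_column(self, position: int) -> Optional[int]:
        return self.position_to_column.get(position)

    def pair_to_positions(
        self, col_i: int, col_j: int
    ) -> Optional[tuple[int, int]]:
        a, b = self.to_position(col_i), self.to_position(col_j)
        if a is None or b is None:
            return None
        return (min(a, b), max(a, b))


def build_position_map(alignment: Alignment, reference_sequence_id: str) -> PositionMap:
    if reference_sequence_id not in alignment.sequence_ids:
        raise ValueError(
            f"reference sequence {reference_sequence_id!r} not in alignment"
        )
    row = alignment.row(reference_sequence_id)
    col_to_pos: dict[int, Optional[int]] = {}
    pos_to_col: dict[int, int] = {}
    pos = 0
    for col, char in enumerate(row, start=1):
        if char == GAP:
            col_to_pos[col] = None
        else:
            pos += 1
            col_to_pos[col] = pos
            pos_to_col[pos] = col
    return PositionMap(col_to_pos, pos_to_col)
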