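from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper

from rnacov import (Alignment, CovariationModel, Phylogeny, SynthSpec,
                    simulate)


def star_phylogeny(pair_types: list[str]) -> tuple[Phylogeny, Alignment]:
    """Root with one leaf per pair type string; 2-column alignment."""
    phylo = Phylogeny()
    root = phylo.add_node(None)
    ids, rows = [], []
    for k, t in enumerate(pair_types):
        leaf = phylo.add_node(root)
        sid = f"s{k}"
        phylo.leaf_to_sequence[leaf] = sid
        ids.append(sid)
        rows.append(t.replace(":", ""))
    return phylo, Alignment(ids, rows)


def phylogeny_from_nested(nested) -> tuple[Phylogeny, Alignment]:
    """Build a Phylogeny + 2-column Alignment from a nested-tuple tree whose
    leaves are pair-type strings (the oracle's representation)."""
    phylo = Phylogeny()
    ids, rows = [], []

    def build(sub, parent):
        node = phylo.add_node(parent)
        if isinstance(sub, str):
            sid = f"s{len(ids)}"
            phylo.leaf_to_sequence[node] = sid
            ids.append(sid)
            rows.append(sub.replace(":", ""))
        else:
            for child in sub:
                build(child, node)

    build(nested, None)
    return phylo, Alignment(ids, rows)


@pytest.fixture(scope="session")
def synth_default():
    """The generator's default study conditions at its default seed."""
    return simulate(SynthSpec())


@pytest.fixture(scope="session")
def fitted_default(synth_default):
    alignment, phylogeny, truth = synth_default
    model = CovariationModel(alignment, phylogeny)
    results = model.fit(methods=("CPE", "MIxy", "MIp"))
    return model, results, truth


@pytest.fixture
def tiny_alignment():
    """Four sequences, perfect covariation at columns (1, 2)."""
    return Alignment(["a", "b", "c", "d"], ["AUCA", "AUCA", "GCCA", "GCCA"])
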