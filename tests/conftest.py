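"""Shared fixtures: toy alignments and random additive trees."""

from __future__ import annotations

import numpy as np
import pytest

from barcodetax import BarcodeAlignment, BarcodeRecord, DistanceMatrix
from barcodetax.trees import SupportTree, TreeNode


def make_alignment(entries):
    """entries: iterable of (sample_id, sequence[, species[, locality]])."""
    records = []
    for entry in entries:
        sid, seq = entry[0], entry[1]
        species = entry[2] if len(entry) > 2 else "UNKNOWN"
        locality = entry[3] if len(entry) > 3 else None
        records.append(
            BarcodeRecord(sid, seq, species_label=species, locality_group=locality)
        )
    return BarcodeAlignment(tuple(records))


def matrix_from_pct(labels, pct_values):
    """Distance matrix from a percent-scale array."""
    return DistanceMatrix(tuple(labels), np.asarray(pct_values, dtype=float) / 100.0)


def random_additive_tree(n_leaves: int, rng: np.random.Generator) -> SupportTree:
    """Random unrooted binary tree with strictly positive branch lengths.

    Path distances between its leaves form an additive matrix that NJ must
    recover exactly.
    """
    leaves = [TreeNode(name=f"L{i}") for i in range(3)]
    root = TreeNode(children=list(leaves))
    for nd in leaves:
        nd.branch_length = rng.uniform(0.05, 0.5)
    attachable = list(leaves)
    parent = {id(nd): root for nd in leaves}
    for i in range(3, n_leaves):
        target = attachable[rng.integers(len(attachable))]
        grandparent = parent[id(target)]
        mid = TreeNode(children=[target])
        leaf = TreeNode(name=f"L{i}", branch_length=rng.uniform(0.05, 0.5))
        mid.children.append(leaf)
        old = target.branch_length
        inner = rng.uniform(0.2, 0.8) * old
        mid.branch_length = old - inner
        target.branch_length = inner
        grandparent.children[grandparent.children.index(target)] = mid
        parent[id(mid)] = grandparent
        parent[id(target)] = mid
        parent[id(leaf)] = mid
        attachable += [mid, leaf]
    return SupportTree(root=root)


@pytest.fixture
def rng():
    return np.random.default_rng(20240612)


@pytest.fixture
def two_clade_alignment(rng):
    """Two clearly separated 3-sample clades (inter ~20%, intra ~0.5%)."""
    from barcodetax import SimulationConfig, simulate_dataset

    config = SimulationConfig(
        n_species=2,
        samples_per_species=(3, 3),
        intra_divergence=0.005,
        inter_divergence=0.20,
        seed=99,
    )
    return simulate_dataset(config).alignment
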