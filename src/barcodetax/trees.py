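"""Neighbour-joining trees, bootstrap support, and divergent-lineage detection.

NJ here is the classic Saitou–Nei agglomeration on the Q criterion, made
fully deterministic: when several pairs tie for the minimal Q the pair whose
(lexicographically smallest) representative labels sort first is joined.
Negative branch-length estimates are clamped to zero with the deficit moved
to the sibling branch, which preserves path lengths to the rest of the tree.

Bootstrap support is obtained by resampling alignment columns with
replacement, rebuilding the K2P+NJ tree per replicate, and mapping
bipartition frequencies back onto the full-data tree.

Divergent intraspecific lineages are the single-linkage components of each
species' samples at a divergence cutoff (default 2% K2P); a species is
flagged when it holds two or more lineages and every between-lineage mean
exceeds the cutoff.  Each lineage carries its geographic profile and, when a
support tree is supplied, the bootstrap support of its smallest containing
clade.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .distances import (
    _PURINE,
    DistanceMatrix,
    distance_matrix,
    encode_alignment,
)
from .seq_qc import BarcodeAlignment

logger = logging.getLogger("barcodetax")


# ---------------------------------------------------------------------------
# Tree structure
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """Node of an unrooted tree (stored rooted at a trifurcation)."""

    name: str | None = None
    branch_length: float = 0.0
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for child in self.children:
            out.extend(child.leaves())
        return out

    def leaf_names(self) -> frozenset[str]:
        return frozenset(l.name for l in self.leaves())

    def walk(self):
        yield self
        for child in self.children:
            yield from child.walk()

    def to_newick(self, with_support: bool = True) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.branch_length:.6f}"
            inner = ",".join(fmt(c) for c in node.children)
            label = ""
            if with_support and node.support is not None:
                label = f"{node.support:g}"
            return f"({inner}){label}:{node.branch_length:.6f}"

        inner = ",".join(fmt(c) for c in self.children)
        return f"({inner});"


@dataclass(frozen=True)
class SupportTree:
    """Unrooted tree over sample ids with branch lengths and % supports."""

    root: TreeNode

    @property
    def leaf_names(self) -> frozenset[str]:
        return self.root.leaf_names()

    def bipartitions(self) -> dict[frozenset[str], TreeNode]:
        """Non-trivial bipartitions, keyed by the leaf set under each edge."""
        all_leaves = self.leaf_names
        out: dict[frozenset[str], TreeNode] = {}
        for node in self.root.walk():
            if node is self.root or node.is_leaf:
                continue
            side = node.leaf_names()
            if 1 < len(side) < len(all_leaves) - 1:
                out[side] = node
        return out

    def canonical_splits(self) -> set[frozenset[str]]:
        """Bipartitions canonicalised to the side not holding the min leaf."""
        anchor = min(self.leaf_names)
        all_leaves = self.leaf_names
        return {
            side if anchor not in side else all_leaves - side
            for side in self.bipartitions()
        }

    def path_distances(self) -> DistanceMatrix:
        """Leaf-to-leaf path-length matrix (checks additivity in tests)."""
        labels = sorted(self.leaf_names)
        index = {name: i for i, name in enumerate(labels)}
        n = len(labels)
        values = np.zeros((n, n))

        def below(node: TreeNode) -> dict[str, float]:
            """Leaf -> path length from *node* down to that leaf."""
            if node.is_leaf:
                return {node.name: 0.0}
            out: dict[str, float] = {}
            for child in node.children:
                for name, dist in below(child).items():
                    out[name] = dist + child.branch_length
            return out

        def visit(node: TreeNode) -> None:
            subtrees = []
            for child in node.children:
                subtrees.append(
                    {
                        name: dist + child.branch_length
                        for name, dist in below(child).items()
                    }
                )
                visit(child)
            for a, b in combinations(subtrees, 2):
                for na, da in a.items():
                    for nb, db in b.items():
                        values[index[na], index[nb]] = da + db
                        values[index[nb], index[na]] = da + db

        visit(self.root)
        return DistanceMatrix(tuple(labels), values)

    def to_newick(self, with_support: bool = True) -> str:
        return self.root.to_newick(with_support=with_support)


# ---------------------------------------------------------------------------
# Neighbour-joining
# ---------------------------------------------------------------------------

def nj_tree(matrix: DistanceMatrix) -> SupportTree:
    """Neighbour-joining on a fully defined distance matrix.

    Deterministic: Q-ties are broken by the lexicographically smallest pair
    of cluster representatives (a cluster is represented by its smallest
    member label).
    """
    if len(matrix) < 3:
        raise ValueError("neighbour-joining needs at least 3 labels")
    undef = matrix.undefined_pairs()
    if undef:
        raise ValueError(
            f"distance matrix holds undefined entries, exclude first: {undef[:5]}"
        )
    labels = list(matrix.labels)
    d = matrix.values.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=l) for l in labels]
    reps: list[str] = list(labels)  # representative = min member label
    active = list(range(len(labels)))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        ties = np.argwhere(q <= qmin + 1e-12)
        best = min(
            (tuple(sorted((reps[active[i]], reps[active[j]]))), i, j)
            for i, j in ties
            if i < j
        )
        ai, aj = best[1], best[2]
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = dij / 2.0 + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        # clamp negative estimates, transferring the deficit to the sibling
        if li < 0.0:
            lj += li
            li = 0.0
        if lj < 0.0:
            li += lj
            lj = 0.0
        node_i, node_j = nodes[i], nodes[j]
        node_i.branch_length = li
        node_j.branch_length = lj
        parent = TreeNode(children=[node_i, node_j])
        # new distances to remaining clusters
        new_row = np.zeros(d.shape[0] + 1)
        for k in active:
            if k in (i, j):
                continue
            new_row[k] = (d[i, k] + d[j, k] - dij) / 2.0
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row[:-1]
        d[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        reps.append(min(reps[i], reps[j]))
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    # resolve the final three clusters around a central trifurcation
    a, b, c = active
    la = (d[a, b] + d[a, c] - d[b, c]) / 2.0
    lb = (d[a, b] + d[b, c] - d[a, c]) / 2.0
    lc = (d[a, c] + d[b, c] - d[a, b]) / 2.0
    for node, length in ((nodes[a], la), (nodes[b], lb), (nodes[c], lc)):
        node.branch_length = max(length, 0.0)
    order = sorted((a, b, c), key=lambda k: reps[k])
    root = TreeNode(children=[nodes[k] for k in order])
    return SupportTree(root=root)


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def bootstrap_support(
    alignment: BarcodeAlignment,
    replicates: int = 1000,
    seed: int | None = None,
    exclusions: Sequence[str] = (),
) -> SupportTree:
    """NJ tree with bootstrap supports from column resampling.

    Columns are resampled with replacement ``replicates`` times; the K2P+NJ
    tree is rebuilt per replicate and bipartition frequencies (as % of usable
    replicates) are written onto the full-data tree.  Replicates whose
    resampled matrix contains undefined distances are skipped and counted; a
    warning is logged when more than 10% are lost.  Reproducible given seed.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if seed is None:
        raise ValueError("bootstrap requires an explicit seed")
    logger.info("bootstrap: %d replicates, seed=%d", replicates, seed)
    if exclusions:
        keep = [r for r in alignment.records if r.sample_id not in set(exclusions)]
        alignment = BarcodeAlignment(tuple(keep))
    full = nj_tree(distance_matrix(alignment))
    target = full.bipartitions()

    enc = encode_alignment(alignment)
    n, length = enc.shape
    labels = tuple(alignment.sample_ids)
    rng = np.random.default_rng(seed)
    counts: Counter[frozenset[str]] = Counter()
    skipped = 0
    # per-pair column categories, fixed across replicates: a replicate's
    # pairwise counts are then three matrix-vector products against the
    # column-multiplicity vector
    iu, ju = np.triu_indices(n, k=1)
    a, b = enc[iu], enc[ju]
    comparable = (a < 4) & (b < 4)
    diff = comparable & (a != b)
    same_class = _PURINE[a] == _PURINE[b]
    category = np.stack(
        [comparable, diff & same_class, diff & ~same_class]
    ).astype(np.float32)  # (3, n_pairs, length)
    for _ in range(replicates):
        cols = rng.integers(0, length, size=length)
        mult = np.bincount(cols, minlength=length).astype(np.float32)
        n_comp, n_ts, n_tv = category @ mult
        with np.errstate(divide="ignore", invalid="ignore"):
            p = n_ts / n_comp
            q = n_tv / n_comp
            w1 = 1.0 - 2.0 * p - q
            w2 = 1.0 - 2.0 * q
            valid = (n_comp > 0) & (w1 > 0) & (w2 > 0)
            if not valid.all():
                skipped += 1
                continue
            d = -0.5 * np.log(w1) - 0.25 * np.log(w2)
        values = np.zeros((n, n))
        values[iu, ju] = d
        values[ju, iu] = d
        rep_tree = nj_tree(DistanceMatrix(labels, values))
        anchor = min(labels)
        all_leaves = frozenset(labels)
        for side in rep_tree.bipartitions():
            canon = side if anchor not in side else all_leaves - side
            counts[canon] += 1
    usable = replicates - skipped
    if skipped > 0.1 * replicates:
        logger.warning(
            "bootstrap: %d/%d replicates skipped (undefined distances)",
            skipped, replicates,
        )
    if usable == 0:
        raise ValueError("all bootstrap replicates had undefined distances")
    anchor = min(labels)
    all_leaves = frozenset(labels)
    for side, node in target.items():
        canon = side if anchor not in side else all_leaves - side
        node.support = 100.0 * counts.get(canon, 0) / usable
    return full


# ---------------------------------------------------------------------------
# Divergent intraspecific lineages
# ---------------------------------------------------------------------------

def single_linkage_components(
    values: np.ndarray, cutoff: float
) -> list[list[int]]:
    """Connected components of the graph joining indices with d < cutoff.

    NaN (undefined) distances never join.  Components are returned sorted by
    smallest member index.
    """
    with np.errstate(invalid="ignore"):
        adj = values < cutoff
    np.fill_diagonal(adj, False)
    n_comp, assign = connected_components(csr_matrix(adj), directed=False)
    comps: dict[int, list[int]] = {}
    for idx, c in enumerate(assign):
        comps.setdefault(int(c), []).append(idx)
    return sorted(comps.values(), key=lambda c: c[0])


@dataclass(frozen=True)
class Lineage:
    """One intraspecific molecular lineage."""

    species: str
    lineage_id: str
    sample_ids: tuple[str, ...]
    mean_internal_pct: float           # NaN for singletons
    locality_profile: Mapping[str, int]  # locality group -> sample count
    clade_support: float | None = None
    meets_support: bool | None = None


@dataclass(frozen=True)
class SpeciesLineages:
    species: str
    lineages: tuple[Lineage, ...]
    between_means_pct: Mapping[tuple[str, str], float]
    flagged: bool

    @property
    def n_lineages(self) -> int:
        return len(self.lineages)


@dataclass(frozen=True)
class LineageSet:
    """Per-species lineage partitions at a divergence cutoff (% K2P)."""

    min_divergence_pct: float
    by_species: Mapping[str, SpeciesLineages]

    def flagged_species(self) -> list[str]:
        return [s for s, sl in self.by_species.items() if sl.flagged]


def _mean_pct(values: np.ndarray) -> float:
    vals = values[~np.isnan(values)]
    return float(vals.mean()) if vals.size else float("nan")


def detect_lineages(
    matrix: DistanceMatrix,
    species_labels: Sequence[str],
    locality_groups: Sequence[str | None],
    min_divergence_pct: float = 2.0,
    support_tree: SupportTree | None = None,
    min_support: float = 95.0,
) -> LineageSet:
    """Partition each species into single-linkage lineages at a K2P cutoff.

    A species is flagged as holding divergent lineages when it splits into
    two or more components and every between-lineage mean distance exceeds
    ``min_divergence_pct``.  With a support tree, each lineage is annotated
    with the bootstrap support of the smallest clade containing all its
    samples and whether that support meets ``min_support``.
    """
    if min_divergence_pct <= 0:
        raise ValueError("min_divergence_pct must be positive")
    if len(species_labels) != len(matrix) or len(locality_groups) != len(matrix):
        raise ValueError("label vectors must match the matrix")
    labels = np.asarray(species_labels)
    localities = list(locality_groups)
    clades = support_tree.bipartitions() if support_tree is not None else {}

    by_species: dict[str, SpeciesLineages] = {}
    for sp in sorted(set(labels)):
        idx = np.flatnonzero(labels == sp)
        sub = matrix.values[np.ix_(idx, idx)] * 100.0
        comps = single_linkage_components(sub, min_divergence_pct)
        lineages = []
        for k, comp in enumerate(comps):
            members = idx[comp]
            iu, ju = np.triu_indices(len(comp), k=1)
            internal = _mean_pct(sub[np.ix_(comp, comp)][iu, ju]) if len(comp) > 1 \
                else float("nan")
            profile = Counter(
                localities[m] for m in members if localities[m] is not None
            )
            support = None
            meets = None
            if support_tree is not None:
                member_ids = frozenset(matrix.labels[m] for m in members)
                containing = [
                    (len(side), node)
                    for side, node in clades.items()
                    if member_ids <= side
                ]
                if containing:
                    _, node = min(containing, key=lambda t: t[0])
                    support = node.support
                    meets = support is not None and support >= min_support
            lineages.append(
                Lineage(
                    species=sp,
                    lineage_id=f"{sp}/L{k + 1}",
                    sample_ids=tuple(matrix.labels[m] for m in members),
                    mean_internal_pct=internal,
                    locality_profile=dict(profile),
                    clade_support=support,
                    meets_support=meets,
                )
            )
        between: dict[tuple[str, str], float] = {}
        for (a_i, la), (b_i, lb) in combinations(enumerate(lineages), 2):
            va = [comps[a_i], comps[b_i]]
            vals = sub[np.ix_(va[0], va[1])].ravel()
            between[(la.lineage_id, lb.lineage_id)] = _mean_pct(vals)
        flagged = len(lineages) >= 2 and all(
            m > min_divergence_pct for m in between.values()
        )
        by_species[sp] = SpeciesLineages(
            species=sp,
            lineages=tuple(lineages),
            between_means_pct=between,
            flagged=flagged,
        )
    return LineageSet(min_divergence_pct=min_divergence_pct, by_species=by_species)
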