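"""Neighbor-joining trees from pairwise identity distances and clade tests.

Clade claims of the discovery workflow -- e.g. that a malonyltransferase
groups with its acetyltransferase orthologue rather than with the canonical
malonyltransferase clade, or that a set of P450s falls inside the CYP71
clade -- are topology-level statements.  Neighbor joining on pairwise-identity
distances (d = 1 - identity/100) supports them at this scale without a
multiple sequence alignment.

Tree construction uses the Saitou-Nei neighbor-joining algorithm as
implemented in scikit-bio; negative branch lengths are clamped to zero
(standard practice).  Monophyly is assessed on the unrooted tree's splits
after conceptually rooting on a user-chosen outgroup.
"""

from __future__ import annotations

import itertools
import logging
from pathlib import Path

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

logger = logging.getLogger(__name__)


def distance_from_identity(pairs) -> DistanceMatrix:
    """Build a distance matrix with d = 1 - percent_identity/100.

    ``pairs`` is an iterable of OrthologPair covering every unordered taxon
    pair; a missing pair raises.  Self-distances are zero.
    """
    ident: dict[frozenset, float] = {}
    taxa: set[str] = set()
    for p in pairs:
        taxa.update((p.id_a, p.id_b))
        ident[frozenset((p.id_a, p.id_b))] = p.percent_identity
    order = sorted(taxa)
    data = [[0.0] * len(order) for _ in order]
    for i, j in itertools.combinations(range(len(order)), 2):
        key = frozenset((order[i], order[j]))
        if key not in ident:
            raise ValueError(f"missing pairwise identity for ({order[i]}, {order[j]})")
        d = 1.0 - ident[key] / 100.0
        data[i][j] = data[j][i] = d
    return DistanceMatrix(data, order)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree; taxa are sorted for a deterministic join order.

    Negative branch lengths produced by the NJ formulas are clamped to zero
    with a log entry.
    """
    if len(dm.ids) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    dm = dm.filter(sorted(dm.ids))
    tree = nj(dm, neg_as_zero=False)
    clamped = 0
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            clamped += 1
    if clamped:
        logger.info("clamped %d negative NJ branch length(s) to zero", clamped)
    return tree


def is_monophyletic(tree: TreeNode, taxa_subset, outgroup: str) -> bool:
    """True iff ``taxa_subset`` forms a clade once the tree is rooted on ``outgroup``.

    Equivalently: some split (edge) of the unrooted tree separates exactly the
    subset from everything else, with the outgroup on the far side.
    """
    subset = set(taxa_subset)
    leaves = {t.name for t in tree.tips()}
    unknown = (subset | {outgroup}) - leaves
    if unknown:
        raise KeyError(f"taxa not in tree: {sorted(unknown)}")
    if outgroup in subset:
        raise ValueError("outgroup must not be part of the tested subset")
    if len(subset) <= 1 or subset == leaves - {outgroup}:
        return True
    for node in tree.non_tips(include_self=True):
        below = {t.name for t in node.tips()}
        if below == subset or (leaves - below) == subset:
            return True
    return False


def topology_splits(tree: TreeNode) -> set[frozenset]:
    """Nontrivial bipartitions of the leaf set, one per internal edge.

    Two unrooted topologies on the same taxa are identical iff their split
    sets are equal.  Each split is canonicalized as the smaller side (ties by
    sorted ids) so the representation is rooting-invariant.
    """
    leaves = frozenset(t.name for t in tree.tips())
    splits = set()
    for node in tree.non_tips(include_self=False):
        below = frozenset(t.name for t in node.tips())
        other = leaves - below
        if 1 < len(below) < len(leaves) - 1:
            key = min(below, other, key=lambda s: (len(s), tuple(sorted(s))))
            splits.add(key)
    return splits


def random_tree(n_taxa: int, seed: int, min_branch: float = 0.05, max_branch: float = 1.0) -> TreeNode:
    """Random unrooted binary topology with uniform branch lengths.

    Built by sequential joining of random pairs; intended for generating
    additive test cases whose path distances a correct NJ must invert.
    """
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    rng = np.random.default_rng(seed)
    nodes = [TreeNode(name=f"t{i}") for i in range(n_taxa)]
    for node in nodes:
        node.length = float(rng.uniform(min_branch, max_branch))
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode(length=float(rng.uniform(min_branch, max_branch)))
        parent.extend([nodes[i], nodes[j]])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = TreeNode()
    root.extend(nodes)
    return root


def path_distance_matrix(tree: TreeNode) -> DistanceMatrix:
    """Leaf-to-leaf path-length (patristic) distances of a tree."""
    return tree.tip_tip_distances()


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def read_newick(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")
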