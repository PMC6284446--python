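"""Neighbor-joining tree construction and unrooted monophyly queries.

NJ agglomerates the pair (i, j) minimizing the Studier–Keppler criterion

    Q(i, j) = (n - 2) * d(i, j) - R(i) - R(j),      R(k) = sum_m d(k, m),

with branch lengths from the standard split formula

    l_i = d(i, j) / 2 + (R(i) - R(j)) / (2 * (n - 2)),   l_j = d(i, j) - l_i.

On an additive (tree-realizable) matrix this recovers the generating
topology and branch lengths exactly.  Ties in Q are broken toward the
smallest (i, j) index pair in current matrix order, so trees are
bit-reproducible.  A negative branch length is clamped to zero with the
deficit moved to its sister branch, preserving l_i + l_j = d(i, j).

Trees are :class:`dendropy.Tree` objects; they are unrooted (the seed node
is the trifurcating center), so monophyly of a label set means that some
edge bipartitions the leaves into exactly that set versus the rest.
"""

from __future__ import annotations

import logging
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from .distances import DistanceMatrix
from .io_taxa import TaxonomyRecord

__all__ = [
    "nj",
    "is_monophyletic",
    "taxon_monophyly_table",
    "bipartitions",
    "patristic_distances",
]

logger = logging.getLogger("barcodegap.nj")

UNDEFINED_POLICIES = ("drop-specimen", "strict")


def _drop_undefined(dm: DistanceMatrix, policy: str) -> DistanceMatrix:
    mask = np.isnan(dm.values)
    np.fill_diagonal(mask, False)
    if not mask.any():
        return dm
    if policy == "strict":
        i, j = np.nonzero(np.triu(mask, k=1))
        pairs = [(dm.ids[a], dm.ids[b]) for a, b in zip(i, j)]
        raise ValueError(f"undefined distances present (policy=strict): {pairs}")
    # greedy vertex cover of the undefined-pair graph, highest degree first
    keep = np.ones(len(dm.ids), dtype=bool)
    work = mask.copy()
    while work.any():
        deg = work.sum(axis=1)
        victim = int(np.argmax(deg))
        keep[victim] = False
        work[victim, :] = False
        work[:, victim] = False
    dropped = [s for s, k in zip(dm.ids, keep) if not k]
    logger.warning("nj: dropping specimens with undefined distances: %s", dropped)
    kept_ids = [s for s, k in zip(dm.ids, keep) if k]
    return dm.submatrix(kept_ids)


def nj(dm: DistanceMatrix, undefined: str = "drop-specimen") -> dendropy.Tree:
    """Build the neighbor-joining tree from a distance matrix.

    ``undefined`` selects how NaN entries are handled: ``"drop-specimen"``
    (default) removes a greedily-chosen minimal set of specimens covering
    all undefined pairs; ``"strict"`` raises, naming the offending pairs.
    """
    if undefined not in UNDEFINED_POLICIES:
        raise ValueError(f"unknown undefined-distance policy {undefined!r}")
    if len(dm) < 2:
        raise ValueError("need at least 2 specimens to build a tree")
    dm = _drop_undefined(dm, undefined)
    if len(dm) < 2:
        raise ValueError("fewer than 2 specimens remain after dropping undefined")

    tns = dendropy.TaxonNamespace()
    nodes: list[dendropy.Node] = []
    for label in dm.ids:
        taxon = tns.new_taxon(label=label)
        nodes.append(dendropy.Node(taxon=taxon))

    D = dm.values.astype(float).copy()

    if len(nodes) == 2:
        root = dendropy.Node()
        half = D[0, 1] / 2.0
        for node in nodes:
            root.add_child(node)
            node.edge.length = half
        tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
        tree.is_rooted = False
        return tree

    while len(nodes) > 3:
        n = D.shape[0]
        R = D.sum(axis=1)
        Q = (n - 2) * D - R[:, None] - R[None, :]
        np.fill_diagonal(Q, np.inf)
        # row-major argmin -> first occurrence is the smallest (i, j), i < j
        flat = int(np.argmin(Q))
        i, j = divmod(flat, n)
        if i > j:
            i, j = j, i
        dij = D[i, j]
        li = 0.5 * dij + (R[i] - R[j]) / (2.0 * (n - 2))
        lj = dij - li
        if li < 0.0:
            lj += li
            li = 0.0
        elif lj < 0.0:
            li += lj
            lj = 0.0
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        new_row = 0.5 * (D[i, :] + D[j, :] - dij)
        D[i, :] = new_row
        D[:, i] = new_row
        D[i, i] = 0.0
        D = np.delete(np.delete(D, j, axis=0), j, axis=1)
        nodes[i] = parent
        del nodes[j]

    # final 3-node star: closed-form branch lengths to the center
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    lengths = [
        (d01 + d02 - d12) / 2.0,
        (d01 + d12 - d02) / 2.0,
        (d02 + d12 - d01) / 2.0,
    ]
    center = dendropy.Node()
    for node, length in zip(nodes, lengths):
        center.add_child(node)
        node.edge.length = max(length, 0.0)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=center)
    tree.is_rooted = False
    return tree


def _leaf_label(node: dendropy.Node) -> str:
    return node.taxon.label if node.taxon is not None else str(node)


def bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """All edge-induced leaf bipartitions, each as the side not containing
    an (arbitrary) reference leaf — a canonical form independent of rooting."""
    leaves = frozenset(_leaf_label(l) for l in tree.leaf_node_iter())
    ref = min(leaves)
    out: set[frozenset[str]] = set()
    below: dict[dendropy.Node, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = frozenset([_leaf_label(node)])
        else:
            below[node] = frozenset().union(*(below[c] for c in node.child_nodes()))
        if node.parent_node is not None:
            side = below[node]
            out.add(side if ref not in side else leaves - side)
    return out


def is_monophyletic(tree: dendropy.Tree, labels: Sequence[str] | set[str]) -> bool:
    """Whether some edge of the unrooted tree separates exactly ``labels``
    from all other leaves.  Singleton and all-leaf sets are trivially
    monophyletic.  Raises ``KeyError`` for labels absent from the tree."""
    leaves = frozenset(_leaf_label(l) for l in tree.leaf_node_iter())
    want = frozenset(labels)
    unknown = want - leaves
    if unknown:
        raise KeyError(f"labels not in tree: {sorted(unknown)}")
    if len(want) <= 1 or want == leaves:
        return True
    ref = min(leaves)
    canon = want if ref not in want else leaves - want
    return canon in bipartitions(tree)


def taxon_monophyly_table(
    tree: dendropy.Tree, taxonomy: dict[str, TaxonomyRecord]
) -> pd.DataFrame:
    """Monophyly flag for every species, genus and subfamily on the tree.

    Single-specimen taxa are trivially monophyletic.  Returns a DataFrame
    with columns ``level, taxon, n_specimens, monophyletic``.
    """
    leaves = {_leaf_label(l) for l in tree.leaf_node_iter()}
    parts = bipartitions(tree)
    all_leaves = frozenset(leaves)
    ref = min(all_leaves)

    def check(members: frozenset[str]) -> bool:
        if len(members) <= 1 or members == all_leaves:
            return True
        canon = members if ref not in members else all_leaves - members
        return canon in parts

    groups: dict[tuple[str, str], set[str]] = {}
    for sid in leaves:
        rec = taxonomy[sid]
        for level, name in (
            ("species", rec.species),
            ("genus", rec.genus),
            ("subfamily", rec.subfamily),
        ):
            groups.setdefault((level, name), set()).add(sid)
    rows = [
        {
            "level": level,
            "taxon": name,
            "n_specimens": len(members),
            "monophyletic": check(frozenset(members)),
        }
        for (level, name), members in sorted(groups.items())
    ]
    return pd.DataFrame(rows)


def patristic_distances(tree: dendropy.Tree) -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix of a tree (for checks and tests)."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    out = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            out[a, b] = out[b, a] = pdm.patristic_distance(taxa[a], taxa[b])
    return DistanceMatrix(labels, out)
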