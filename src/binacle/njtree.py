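"""Neighbour-joining phenograms with nonparametric bootstrap supports.

Saitou–Nei neighbour joining with the Studier–Keppler O(n^3) update.  On an
additive distance matrix the tree's path-length metric reproduces the input
exactly — the classical consistency guarantee, and the main correctness
oracle for this module.  Trees are held as unrooted dendropy trees; Newick
output carries bootstrap supports as internal node labels.

Ties in the Q matrix are broken deterministically toward the
lexicographically smallest pair of subtree keys (a subtree's key is the
smallest leaf id it contains).  Negative branch-length estimates are
clamped to zero for display, with the raw estimate retained as an edge
annotation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import dendropy
import numpy as np

from .distances import DistanceMatrix, encode, matrix_from_codes
from .qc import AlignedMatrix


class TreeError(ValueError):
    pass


class Tree:
    """Thin wrapper over an unrooted dendropy tree keyed by leaf ids."""

    def __init__(self, dtree: dendropy.Tree):
        dtree.is_rooted = False
        self._t = dtree

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._t

    @property
    def leaf_ids(self) -> list:
        return sorted(l.taxon.label for l in self._t.leaf_node_iter())

    def newick(self) -> str:
        return self._t.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        ).strip()

    @classmethod
    def from_newick(cls, s: str) -> "Tree":
        t = dendropy.Tree.get(
            data=s,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
        return cls(t)

    def bipartitions(self) -> set:
        """Canonical internal bipartitions as frozensets of leaf ids.

        Each internal edge splits the leaves in two; the side *not*
        containing the overall smallest leaf id is the canonical
        representative (orientation-free for unrooted comparison).
        """
        leaves = self.leaf_ids
        if not leaves:
            return set()
        anchor = leaves[0]
        all_leaves = frozenset(leaves)
        out = set()
        for node in self._t.preorder_node_iter():
            if node is self._t.seed_node or node.is_leaf():
                continue
            below = frozenset(l.taxon.label for l in node.leaf_iter())
            if len(below) < 2 or len(below) > len(leaves) - 2:
                continue
            side = all_leaves - below if anchor in below else below
            out.add(side)
        return out

    def path_distance_matrix(self) -> DistanceMatrix:
        pdm = self._t.phylogenetic_distance_matrix()
        ids = self.leaf_ids
        taxa = {t.label: t for t in self._t.taxon_namespace}
        n = len(ids)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = pdm.patristic_distance(taxa[ids[i]], taxa[ids[j]])
        return DistanceMatrix(ids=ids, d=d, compared_sites=np.zeros((n, n), dtype=int))

    def supports(self) -> dict:
        """Map canonical bipartition -> integer support (where assigned)."""
        leaves = self.leaf_ids
        anchor = leaves[0]
        all_leaves = frozenset(leaves)
        out = {}
        for node in self._t.preorder_node_iter():
            if node is self._t.seed_node or node.is_leaf() or node.label is None:
                continue
            below = frozenset(l.taxon.label for l in node.leaf_iter())
            if len(below) < 2 or len(below) > len(leaves) - 2:
                continue
            side = all_leaves - below if anchor in below else below
            out[side] = int(node.label)
        return out


def _clamp(node, length: float):
    if length < 0:
        node.edge.length = 0.0
        node.edge.annotations.add_new("raw_length", f"{length:.12g}")
    else:
        node.edge.length = float(length)


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Build the NJ tree for a complete distance matrix (n >= 3)."""
    n = len(dm.ids)
    if n < 3:
        raise TreeError(f"neighbour joining needs >= 3 taxa, got {n}")
    if np.isnan(dm.d).any():
        raise TreeError("distance matrix contains flagged (NaN) pairs")

    # canonical taxon order: float summation order (hence tie behaviour)
    # must not depend on how the caller happened to order the rows
    order = sorted(range(n), key=lambda i: dm.ids[i])
    ids = [dm.ids[i] for i in order]

    ns = dendropy.TaxonNamespace(ids)
    tree = dendropy.Tree(taxon_namespace=ns)
    nodes = []
    for label in ids:
        nd = dendropy.Node(taxon=ns.get_taxon(label))
        nodes.append(nd)
    keys = list(ids)  # key = smallest leaf id in each subtree
    d = dm.d[np.ix_(order, order)].astype(float)
    d = (d + d.T) / 2  # guard against float-level asymmetry in the input

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        # (r_i + r_j) grouped so q is exactly symmetric in floating point
        q = (m - 2) * d - (r[:, None] + r[None, :])
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                if q[i, j] == qmin:
                    pair = tuple(sorted((keys[i], keys[j])))
                    if best is None or pair < best[0]:
                        best = (pair, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        _clamp(nodes[i], li)
        _clamp(nodes[j], lj)
        dnew = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d2 = np.zeros((len(keep) + 1, len(keep) + 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = dnew[keep]
        d = d2
        nodes = [nodes[k] for k in keep] + [parent]
        keys = [keys[k] for k in keep] + [min(best[0])]

    # final three subtrees: closed-form star resolution
    center = dendropy.Node()
    (a, b, c) = nodes
    va = (d[0, 1] + d[0, 2] - d[1, 2]) / 2
    vb = (d[0, 1] + d[1, 2] - d[0, 2]) / 2
    vc = (d[0, 2] + d[1, 2] - d[0, 1]) / 2
    for nd, v in ((a, va), (b, vb), (c, vc)):
        center.add_child(nd)
        _clamp(nd, v)
    tree.seed_node = center
    return Tree(tree)


def bootstrap_supports(
    alignment: AlignedMatrix,
    reps: int = 500,
    seed: int = 0,
    min_overlap: int = 0,
) -> Tree:
    """NJ tree with bipartition bootstrap supports.

    Alignment columns are resampled with replacement per replicate
    (replicate r uses the RNG stream ``[seed, r]``); support of an internal
    edge is the percentage of replicate trees containing its bipartition.
    """
    if reps < 1:
        raise TreeError("bootstrap needs reps >= 1")
    if len(alignment.ids) < 4:
        raise TreeError("bootstrap supports need >= 4 rows")
    codes = encode(alignment.rows)
    L = codes.shape[1]
    base_dm = matrix_from_codes(list(alignment.ids), codes, min_overlap=min_overlap)
    tree = neighbor_joining(base_dm)
    target = {bp: 0 for bp in tree.bipartitions()}
    for r in range(reps):
        rng = np.random.default_rng([seed, r])
        cols = rng.integers(0, L, size=L)
        dm_r = matrix_from_codes(list(alignment.ids), codes[:, cols], min_overlap=min_overlap)
        if np.isnan(dm_r.d).any():
            continue  # resample produced a zero-overlap pair; skip replicate
        for bp in neighbor_joining(dm_r).bipartitions():
            if bp in target:
                target[bp] += 1

    leaves = tree.leaf_ids
    anchor = leaves[0]
    all_leaves = frozenset(leaves)
    t = tree.dendropy_tree
    for node in t.preorder_node_iter():
        if node is t.seed_node or node.is_leaf():
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        if len(below) < 2 or len(below) > len(leaves) - 2:
            continue
        side = all_leaves - below if anchor in below else below
        node.label = str(round(100 * target[side] / reps))
    return tree


@dataclass
class GroupSummary:
    label: str
    n_leaves: int
    monophyletic: bool
    max_depth: float


def collapse_by_group(tree: Tree, group: dict) -> list:
    """Collapse leaves by label: wedge size, monophyly and depth per label.

    ``max_depth`` is the largest within-group path distance (the height of
    the collapsed wedge); groups whose leaves do not form one clade of the
    unrooted tree are reported non-monophyletic.
    """
    leaves = tree.leaf_ids
    missing = [l for l in leaves if l not in group]
    if missing:
        raise TreeError(f"group map missing leaves: {missing[:5]}")
    bps = tree.bipartitions()
    anchor = leaves[0]
    all_leaves = frozenset(leaves)
    pdm = tree.path_distance_matrix()
    out = []
    for label in sorted({group[l] for l in leaves}, key=str):
        members = frozenset(l for l in leaves if group[l] == label)
        if len(members) in (1, len(leaves)):
            mono = True
        else:
            side = all_leaves - members if anchor in members else members
            mono = side in bps or len(members) == len(leaves) - 1
        idx = [pdm.index(m) for m in members]
        depth = float(pdm.d[np.ix_(idx, idx)].max()) if len(idx) > 1 else 0.0
        out.append(GroupSummary(label=label, n_leaves=len(members), monophyletic=mono, max_depth=depth))
    return out
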