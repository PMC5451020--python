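"""Neighbour-joining trees with column-resampling bootstrap support.

Saitou & Nei agglomeration on a distance matrix: repeatedly join the pair
(i, j) minimizing Q(i, j) = (r - 2) d(i, j) - sum_k d(i, k) - sum_k d(j, k),
with limb lengths from the standard split formula.  NJ is exact on additive
matrices.  Ties in Q are broken lexicographically (each cluster is keyed by
the smallest leaf name it contains), so the output is deterministic.
Negative limb lengths are clamped to zero with the deficit transferred to
the sibling limb, preserving the joined pair's distance.

Bootstrap support follows the reference-topology convention: the tree built
from the full alignment is kept, alignment columns are resampled with
replacement, and each internal edge of the reference tree is annotated with
the percentage of replicate trees containing the same bipartition.
Replicates whose resampled matrix contains UNDEFINED distances are dropped
and logged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .distance import DistanceMatrix, UNDEFINED, _patterns_encoded, _MISSING
from .distance import encode as _encode
from .distance import k2p_from_proportions

logger = logging.getLogger(__name__)


@dataclass
class TreeNode:
    """Node of a phylogenetic tree; ``length`` is the edge to the parent."""

    name: str = ""
    length: float | None = None
    support: int | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_names(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out: list[str] = []
        for child in self.children:
            out.extend(child.leaf_names())
        return out

    def _newick(self) -> str:
        if self.is_leaf:
            label = self.name
        else:
            inner = ",".join(c._newick() for c in self.children)
            label = f"({inner})" + ("" if self.support is None else str(self.support))
        if self.length is None:
            return label
        return f"{label}:{self.length:.6f}"


@dataclass
class PhyloTree:
    """Unrooted tree represented with a (possibly trifurcating) root node."""

    root: TreeNode

    @property
    def leaves(self) -> list[str]:
        return self.root.leaf_names()

    def to_newick(self) -> str:
        return self.root._newick() + ";"

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        import dendropy

        dtree = dendropy.Tree.get(data=text, schema="newick")

        def convert(dnode) -> TreeNode:
            node = TreeNode(
                name=dnode.taxon.label if dnode.taxon else (dnode.label or ""),
                length=dnode.edge.length,
            )
            if dnode.child_nodes():
                label = dnode.label
                if label is not None:
                    try:
                        node.support = int(round(float(label)))
                        node.name = ""
                    except ValueError:
                        pass
                node.children = [convert(c) for c in dnode.child_nodes()]
            return node

        root = convert(dtree.seed_node)
        root.length = None
        return cls(root)

    def path_length_matrix(self) -> tuple[list[str], np.ndarray]:
        """Leaf-to-leaf patristic distances (sum of branch lengths)."""
        adjacency: dict[int, list[tuple[int, float]]] = {}
        leaf_index: dict[str, int] = {}
        counter = 0

        def walk(node: TreeNode) -> int:
            nonlocal counter
            me = counter
            counter += 1
            adjacency.setdefault(me, [])
            if node.is_leaf:
                leaf_index[node.name] = me
            for child in node.children:
                cid = walk(child)
                w = child.length or 0.0
                adjacency[me].append((cid, w))
                adjacency[cid].append((me, w))
            return me

        walk(self.root)
        ids = sorted(leaf_index)
        out = np.zeros((len(ids), len(ids)))
        for a, name in enumerate(ids):
            # Dijkstra unnecessary: trees have unique paths; BFS accumulates.
            dist = {leaf_index[name]: 0.0}
            stack = [leaf_index[name]]
            while stack:
                cur = stack.pop()
                for nxt, w in adjacency[cur]:
                    if nxt not in dist:
                        dist[nxt] = dist[cur] + w
                        stack.append(nxt)
            for b, other in enumerate(ids):
                out[a, b] = dist[leaf_index[other]]
        return ids, out

    def _internal_edges(self) -> list[tuple[TreeNode, frozenset]]:
        """(child node, leafset below it) for internal, non-root edges."""
        total = len(self.leaves)
        edges: list[tuple[TreeNode, frozenset]] = []

        def walk(node: TreeNode, is_root: bool) -> frozenset:
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset().union(*(walk(c, False) for c in node.children))
            if not is_root and 2 <= len(below) <= total - 2:
                edges.append((node, below))
            return below

        walk(self.root, True)
        return edges

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial splits, each canonicalized to the side that excludes
        the alphabetically first leaf (orientation-free representation)."""
        ref = min(self.leaves)
        universe = frozenset(self.leaves)
        out = set()
        for _node, below in self._internal_edges():
            out.add(universe - below if ref in below else below)
        return out

    def has_clade(self, tips) -> bool:
        """True when the tip set is separated by some edge (monophyly in the
        unrooted sense).  Singletons and the full leaf set are trivially true."""
        tips = frozenset(tips)
        universe = frozenset(self.leaves)
        if not tips <= universe:
            raise KeyError("tips not in tree")
        # leaf edges separate singletons (and their complements) trivially
        if len(tips) <= 1 or len(universe - tips) <= 1:
            return True
        ref = min(universe)
        canonical = universe - tips if ref in tips else tips
        return canonical in self.bipartitions()

    def clade_support(self, tips) -> int | None:
        """Bootstrap support of the edge separating ``tips`` from the rest.

        None when no such edge exists (the tips are not a clade) or the edge
        carries no support annotation.
        """
        tips = frozenset(tips)
        universe = frozenset(self.leaves)
        for node, below in self._internal_edges():
            if below == tips or below == universe - tips:
                return node.support
        return None


def _check_defined(matrix: DistanceMatrix) -> None:
    bad = []
    n = len(matrix.ids)
    for i in range(n):
        for j in range(i + 1, n):
            if math.isnan(matrix.values[i, j]):
                bad.append((matrix.ids[i], matrix.ids[j]))
    if bad:
        raise ValueError(f"UNDEFINED distances for pairs: {bad[:10]}")


def neighbor_joining(matrix: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbour joining (deterministic, exact on additive input)."""
    n = len(matrix.ids)
    if n < 3:
        raise ValueError("neighbour joining needs at least 3 taxa")
    _check_defined(matrix)

    size = 2 * n - 2
    D = np.zeros((size, size))
    D[:n, :n] = matrix.values
    nodes: list[TreeNode] = [TreeNode(name=i) for i in matrix.ids]
    keys: list[str] = list(matrix.ids)  # smallest leaf name in each cluster
    active = list(range(n))
    nxt = n

    while len(active) > 3:
        r = len(active)
        sub = D[np.ix_(active, active)]
        row_sums = sub.sum(axis=1)
        Q = (r - 2) * sub - row_sums[:, None] - row_sums[None, :]
        # evaluation order makes Q asymmetric at 1 ulp; use one triangle only
        iu = np.triu_indices(r, k=1)
        qmin = Q[iu].min()
        best = None
        for a in range(r):
            for b in range(a + 1, r):
                if Q[a, b] == qmin:
                    key = tuple(sorted((keys[active[a]], keys[active[b]])))
                    if best is None or key < best[0]:
                        best = (key, a, b)
        _, a, b = best
        i, j = active[a], active[b]
        dij = D[i, j]
        limb_i = 0.5 * dij + (row_sums[a] - row_sums[b]) / (2 * (r - 2))
        limb_j = dij - limb_i
        if limb_i < 0:
            limb_j += limb_i
            limb_i = 0.0
        if limb_j < 0:
            limb_i += limb_j
            limb_j = 0.0
        limb_i = max(limb_i, 0.0)
        limb_j = max(limb_j, 0.0)
        nodes[i].length = limb_i
        nodes[j].length = limb_j
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes.append(parent)
        keys.append(min(keys[i], keys[j]))
        u = nxt
        nxt += 1
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (D[i, k] + D[j, k] - dij)
            D[u, k] = D[k, u] = duk
        active = [k for k in active if k not in (i, j)] + [u]

    x, y, z = active
    lx = 0.5 * (D[x, y] + D[x, z] - D[y, z])
    ly = 0.5 * (D[x, y] + D[y, z] - D[x, z])
    lz = 0.5 * (D[x, z] + D[y, z] - D[x, y])
    for idx, limb in zip((x, y, z), (lx, ly, lz)):
        nodes[idx].length = max(limb, 0.0)
    ordered = sorted((x, y, z), key=lambda idx: keys[idx])
    root = TreeNode(children=[nodes[idx] for idx in ordered])
    return PhyloTree(root)


def _k2p_matrix_encoded(ids: list[str], enc: np.ndarray) -> DistanceMatrix:
    m = len(ids)
    values = np.zeros((m, m))
    counts = np.zeros((m, m), dtype=int)
    for i in range(m):
        counts[i, i] = int((enc[i] != _MISSING).sum())
        for j in range(i + 1, m):
            n, P, Q = _patterns_encoded(enc[i], enc[j])
            values[i, j] = values[j, i] = (
                UNDEFINED if n == 0 else k2p_from_proportions(P, Q)
            )
            counts[i, j] = counts[j, i] = n
    return DistanceMatrix(ids, values, counts)


def bootstrap_support(
    alignment,
    replicates: int = 2000,
    seed: int = 0,
    deletion: str = "pairwise",
) -> PhyloTree:
    """NJ tree from K2P distances with column-resampling bootstrap supports.

    The reference topology is built from the full alignment; each of its
    internal edges receives the percentage (integer, 0-100) of successful
    replicates whose NJ tree contains the same bipartition.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    seqs = list(alignment)
    ids = [s.specimen_id for s in seqs]
    enc = np.stack([_encode(s) for s in seqs])
    if deletion == "complete":
        enc = enc[:, (enc != _MISSING).all(axis=0)]
    ref_tree = neighbor_joining(_k2p_matrix_encoded(ids, enc))

    rng = np.random.default_rng(seed)
    length = enc.shape[1]
    split_counts: dict[frozenset, int] = {}
    kept = 0
    dropped = 0
    for _ in range(replicates):
        cols = rng.integers(0, length, size=length)
        boot = _k2p_matrix_encoded(ids, enc[:, cols])
        if np.isnan(boot.values[np.triu_indices(len(ids), k=1)]).any():
            dropped += 1
            continue
        kept += 1
        for split in neighbor_joining(boot).bipartitions():
            split_counts[split] = split_counts.get(split, 0) + 1
    if dropped:
        logger.warning("dropped %d/%d bootstrap replicates (UNDEFINED)", dropped, replicates)
    if kept == 0:
        raise ValueError("all bootstrap replicates had UNDEFINED distances")

    ref = min(ref_tree.leaves)
    universe = frozenset(ref_tree.leaves)
    for node, below in ref_tree._internal_edges():
        canonical = universe - below if ref in below else below
        node.support = int(round(100.0 * split_counts.get(canonical, 0) / kept))
    return ref_tree


def write_support_table(tree: PhyloTree, path) -> None:
    """TSV of bipartition (semicolon-joined smaller side) -> support."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("bipartition\tsupport\n")
        for node, below in tree._internal_edges():
            if node.support is not None:
                fh.write(";".join(sorted(below)) + f"\t{node.support}\n")
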