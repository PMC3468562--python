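"""Neighbor-joining trees with nonparametric bootstrap supports.

Classical Saitou–Nei NJ over a K2P distance matrix: at each step the pair
minimising Q(i,j) = (n-2) d(i,j) - sum_k d(i,k) - sum_k d(j,k) is joined,
branch lengths follow the standard divergence formula and the matrix is
reduced with d(u,k) = (d(i,k) + d(j,k) - d(i,j)) / 2.  Ties in Q are broken
by the smallest (row, column) index pair; negative branch lengths are
clamped to zero with the deficit transferred to the sister branch.

Bootstrap supports resample alignment columns with replacement, rebuild the
tree per replicate, and report for every internal edge of the full-data tree
the percentage of replicates containing the same leaf bipartition.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

from .distances import DistanceMatrix, pairwise_matrix
from .seq_io import BarcodeAlignment, BarcodeRecord

__all__ = ["Tree", "neighbor_joining", "bootstrap_support", "species_monophyly"]


class Tree:
    """Unrooted tree: integer nodes, weighted edges, leaf labels, supports.

    Supports are percentages (0-100) attached to internal edges; edges are
    keyed by frozenset({u, v}).
    """

    def __init__(self) -> None:
        self.adj: dict[int, dict[int, float]] = {}
        self.labels: dict[int, str] = {}
        self.supports: dict[frozenset, float] = {}
        self._next = 0

    # -- construction -----------------------------------------------------
    def add_node(self, label: str | None = None) -> int:
        nid = self._next
        self._next += 1
        self.adj[nid] = {}
        if label is not None:
            self.labels[nid] = label
        return nid

    def add_edge(self, u: int, v: int, length: float) -> None:
        self.adj[u][v] = float(length)
        self.adj[v][u] = float(length)

    # -- queries ----------------------------------------------------------
    @property
    def leaf_names(self) -> list[str]:
        return sorted(self.labels.values())

    def leaves(self) -> list[int]:
        return sorted(self.labels)

    def edges(self) -> list[tuple[int, int, float]]:
        seen = set()
        out = []
        for u, nbrs in self.adj.items():
            for v, w in nbrs.items():
                key = frozenset((u, v))
                if key not in seen:
                    seen.add(key)
                    out.append((u, v, w))
        return out

    def total_length(self) -> float:
        return sum(w for _, _, w in self.edges())

    def degree(self, node: int) -> int:
        return len(self.adj[node])

    def _side_leaves(self, u: int, v: int) -> set[str]:
        """Leaf labels reachable from v when the edge (u,v) is removed."""
        out: set[str] = set()
        stack = [v]
        seen = {u, v}
        while stack:
            node = stack.pop()
            if node in self.labels:
                out.add(self.labels[node])
            for nbr in self.adj[node]:
                if nbr not in seen:
                    seen.add(nbr)
                    stack.append(nbr)
        return out

    def bipartitions(self) -> dict[frozenset, tuple[int, int]]:
        """Map each internal edge to its canonical leaf bipartition.

        A bipartition is stored as the frozenset of leaf names on the side
        NOT containing the lexicographically smallest leaf, so that the
        representation is independent of orientation and leaf input order.
        Trivial (single-leaf) splits are omitted.
        """
        anchor = min(self.leaf_names)
        all_leaves = set(self.leaf_names)
        out: dict[frozenset, tuple[int, int]] = {}
        for u, v, _ in self.edges():
            side = self._side_leaves(u, v)
            if anchor in side:
                side = all_leaves - side
            if 1 < len(side) < len(all_leaves) - 1:
                out[frozenset(side)] = (u, v)
        return out

    def path_length_matrix(self, order: Sequence[str] | None = None) -> np.ndarray:
        """Leaf-to-leaf path lengths, rows/cols in ``order`` (default sorted)."""
        names = list(order) if order is not None else self.leaf_names
        node_of = {lab: nid for nid, lab in self.labels.items()}
        n = len(names)
        out = np.zeros((n, n))
        for i, name in enumerate(names):
            # Dijkstra-free: tree, so simple DFS accumulating distance
            src = node_of[name]
            dist = {src: 0.0}
            stack = [src]
            while stack:
                node = stack.pop()
                for nbr, w in self.adj[node].items():
                    if nbr not in dist:
                        dist[nbr] = dist[node] + w
                        stack.append(nbr)
            for j, other in enumerate(names):
                out[i, j] = dist[node_of[other]]
        return out

    # -- serialisation ----------------------------------------------------
    def to_newick(self) -> str:
        """Newick string; supports become internal-node labels."""
        # root at an internal node if one exists, else at the first leaf
        internal = [n for n in self.adj if n not in self.labels]
        root = internal[0] if internal else next(iter(self.adj))

        def render(node: int, parent: int | None) -> str:
            children = [c for c in self.adj[node] if c != parent]
            if not children:
                name = self.labels.get(node, "")
                return name
            inner = ",".join(
                f"{render(c, node)}:{self.adj[node][c]:.10g}" for c in children
            )
            label = ""
            if parent is not None:
                sup = self.supports.get(frozenset((node, parent)))
                if sup is not None:
                    label = f"{sup:g}"
            return f"({inner}){label}"

        return render(root, None) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        """Parse Newick (via dendropy); internal-node labels read as supports."""
        dt = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
        tree = cls()
        node_map: dict = {}

        def visit(dnode, parent_id):
            if dnode.is_leaf():
                nid = tree.add_node(dnode.taxon.label if dnode.taxon else dnode.label)
            else:
                nid = tree.add_node()
            node_map[dnode] = nid
            if parent_id is not None:
                length = dnode.edge.length if dnode.edge.length is not None else 0.0
                tree.add_edge(parent_id, nid, length)
                if not dnode.is_leaf() and dnode.label is not None:
                    try:
                        tree.supports[frozenset((parent_id, nid))] = float(dnode.label)
                    except ValueError:
                        pass
            for child in dnode.child_nodes():
                visit(child, nid)

        visit(dt.seed_node, None)
        # suppress the artificial degree-2 root dendropy introduces
        root_id = node_map[dt.seed_node]
        if tree.degree(root_id) == 2 and root_id not in tree.labels:
            (a, wa), (b, wb) = list(tree.adj[root_id].items())
            sup = tree.supports.pop(frozenset((root_id, a)), None)
            if sup is None:
                sup = tree.supports.pop(frozenset((root_id, b)), None)
            del tree.adj[a][root_id]
            del tree.adj[b][root_id]
            del tree.adj[root_id]
            tree.add_edge(a, b, wa + wb)
            if sup is not None:
                tree.supports[frozenset((a, b))] = sup
        return tree


def neighbor_joining(m: DistanceMatrix) -> Tree:
    """Classical NJ on a fully defined distance matrix.

    Raises on undefined (NaN) entries -- callers must impute or drop
    saturated pairs first -- and on n < 3.
    """
    n = len(m.labels)
    if n < 3:
        raise ValueError(f"NJ needs at least 3 taxa, got {n}")
    if np.isnan(m.values).any():
        raise ValueError(
            f"matrix has undefined entries: {m.undefined_pairs()[:5]}"
        )

    tree = Tree()
    nodes = [tree.add_node(lab) for lab in m.labels]
    D = m.values.astype(float).copy()
    active = list(range(n))

    while len(active) > 2:
        k = len(active)
        sub = D[np.ix_(active, active)]
        if k == 3:
            # terminal star: closed-form lengths onto one internal node
            center = tree.add_node()
            for local, idx in enumerate(active):
                # (d_ab + d_ac - d_bc) / 2 for each tip
                others = [x for x in range(3) if x != local]
                length = 0.5 * (
                    sub[local, others[0]] + sub[local, others[1]] - sub[others[0], others[1]]
                )
                tree.add_edge(nodes[idx], center, max(length, 0.0))
            return tree

        rowsum = sub.sum(axis=1)
        Q = (k - 2) * sub - rowsum[:, None] - rowsum[None, :]
        np.fill_diagonal(Q, np.inf)
        # argmin scans row-major: ties resolve to the smallest (row, col)
        flat = int(np.argmin(Q))
        li, lj = divmod(flat, k)
        if li > lj:
            li, lj = lj, li
        i, j = active[li], active[lj]

        dij = sub[li, lj]
        bi = 0.5 * dij + (rowsum[li] - rowsum[lj]) / (2 * (k - 2))
        bj = dij - bi
        # clamp-and-transfer: keep the pair's total length
        if bi < 0:
            bj += bi
            bi = 0.0
        if bj < 0:
            bi += bj
            bj = 0.0
        bi, bj = max(bi, 0.0), max(bj, 0.0)

        u = tree.add_node()
        tree.add_edge(nodes[i], u, bi)
        tree.add_edge(nodes[j], u, bj)

        # grow D with the new node's distances
        new_row = 0.5 * (D[i, active] + D[j, active] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        idx_new = D.shape[0] - 1
        D[idx_new, active] = new_row
        D[active, idx_new] = new_row
        D[idx_new, idx_new] = 0.0
        nodes.append(u)

        active = [x for x in active if x not in (i, j)] + [idx_new]

    # n == 2 at entry is rejected above; loop always returns at k == 3
    raise AssertionError("unreachable")


def _resample_columns(rng: np.random.Generator, L: int) -> np.ndarray:
    return rng.integers(0, L, size=L)


def bootstrap_support(
    aln: BarcodeAlignment,
    kind: str = "k2p_total",
    B: int = 1000,
    seed: int = 0,
    deletion: str = "pairwise",
) -> Tree:
    """Full-data NJ tree with bootstrap supports on internal edges.

    Replicate r resamples alignment columns with replacement using the
    deterministic substream ``default_rng([seed, r])``, so supports are
    reproducible and invariant to leaf input order.  Replicates whose
    distance matrix contains saturated entries are dropped and counted; a
    warning is issued if more than 10% drop.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    # canonical (sorted-id) order everywhere: NJ tie-breaks depend on row
    # order, and identical sequences produce exact ties, so canonicalising
    # makes both the full-data tree and the supports independent of leaf
    # input order
    aln = BarcodeAlignment(
        sorted(aln.records, key=lambda r: r.seq_id), frame_offset=aln.frame_offset
    )
    full = pairwise_matrix(aln, kind=kind, deletion=deletion)
    tree = neighbor_joining(full)
    target = tree.bipartitions()
    counts = {bp: 0 for bp in target}

    cols = aln.length
    mat = aln.matrix()
    ids = aln.seq_ids
    dropped = 0
    completed = 0
    for r in range(B):
        rng = np.random.default_rng([seed, r])
        pick = _resample_columns(rng, cols)
        sub_records = [
            BarcodeRecord(seq_id=ids[i], sequence="".join(mat[i, pick]))
            for i in range(len(ids))
        ]
        rep_aln = BarcodeAlignment(sub_records, frame_offset=aln.frame_offset)
        try:
            rep_m = pairwise_matrix(rep_aln, kind=kind, deletion=deletion)
            rep_tree = neighbor_joining(rep_m)
        except ValueError:
            dropped += 1
            continue
        completed += 1
        rep_bps = set(rep_tree.bipartitions())
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1

    if completed == 0:
        raise ValueError("all bootstrap replicates were dropped")
    if dropped > 0.1 * B:
        warnings.warn(f"{dropped}/{B} bootstrap replicates dropped (saturation)")
    for bp, edge in target.items():
        tree.supports[frozenset(edge)] = 100.0 * counts[bp] / completed
    return tree


def species_monophyly(
    tree: Tree, grouping: Mapping[str, str]
) -> dict[str, tuple[bool, float | None]]:
    """Per-species monophyly on an unrooted tree.

    A species with >= 2 leaves is monophyletic iff some edge bipartition
    isolates exactly its leaves; the supporting edge's bootstrap value (if
    any) is returned alongside.  Singletons are trivially monophyletic.
    """
    leaves = set(tree.leaf_names)
    missing = [l for l in leaves if l not in grouping]
    if missing:
        raise ValueError(f"grouping does not cover leaves: {missing[:5]}")
    bps = tree.bipartitions()
    by_set = {bp: edge for bp, edge in bps.items()}
    out: dict[str, tuple[bool, float | None]] = {}
    species = {}
    for leaf in leaves:
        species.setdefault(grouping[leaf], set()).add(leaf)
    for sp, members in species.items():
        if len(members) < 2:
            out[sp] = (True, None)
            continue
        key = frozenset(members)
        comp = frozenset(leaves - members)
        edge = by_set.get(key) or by_set.get(comp)
        if edge is not None:
            out[sp] = (True, tree.supports.get(frozenset(edge)))
        else:
            out[sp] = (False, None)
    return out
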