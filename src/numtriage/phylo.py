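"""Neighbor-joining trees, column-bootstrap support and clade queries.

The NJ agglomeration uses the standard Q-criterion with a deterministic
tie-break (among minimal-Q pairs, the lexicographically smallest pair of
cluster representative labels is joined), so topologies are reproducible even
on ultrametric or degenerate matrices. Negative branch lengths are clamped to
zero and the clamped deficit is logged.

Bootstrap support for an internal edge is the percentage of column-resampled
replicate trees that contain the same leaf bipartition.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from typing import Iterable, Optional, Sequence

import numpy as np

from .evodist import DistanceMatrix, encode_rows, k2p_matrix_from_codes

logger = logging.getLogger(__name__)


class Node:
    __slots__ = ("name", "length", "support", "children", "parent")

    def __init__(self, name: str = "", length: float = 0.0,
                 support: Optional[float] = None):
        self.name = name
        self.length = length
        self.support = support
        self.children: list["Node"] = []
        self.parent: Optional["Node"] = None

    def add(self, child: "Node") -> None:
        child.parent = self
        self.children.append(child)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()

    def leaf_names(self) -> frozenset:
        return frozenset(n.name for n in self.walk() if n.is_leaf)


class Tree:
    """A rooted representation; NJ output has a trifurcating root (unrooted)."""

    def __init__(self, root: Node):
        self.root = root

    def leaves(self) -> list[Node]:
        return [n for n in self.root.walk() if n.is_leaf]

    def leaf_names(self) -> frozenset:
        return self.root.leaf_names()

    def find_leaf(self, name: str) -> Node:
        for n in self.leaves():
            if n.name == name:
                return n
        raise KeyError(f"leaf {name!r} not in tree")

    def bipartitions(self) -> dict[frozenset, Node]:
        """Nontrivial leaf splits, canonicalized, mapped to the child node
        of the defining edge."""
        all_leaves = self.leaf_names()
        ref = min(all_leaves)
        out: dict[frozenset, Node] = {}
        for node in self.root.walk():
            if node is self.root or node.is_leaf:
                continue
            side = node.leaf_names()
            if len(side) < 2 or len(side) > len(all_leaves) - 2:
                continue
            canon = side if ref not in side else all_leaves - side
            out[canon] = node
        return out

    def leaf_distance(self, a: str, b: str) -> float:
        """Sum of branch lengths along the path between two leaves."""
        pa = self._path_to_root(self.find_leaf(a))
        pb = self._path_to_root(self.find_leaf(b))
        sa, sb = set(id(n) for n in pa), set(id(n) for n in pb)
        d = 0.0
        for n in pa:
            if id(n) in sb:
                break
            d += n.length
        for n in pb:
            if id(n) in sa:
                break
            d += n.length
        return d

    @staticmethod
    def _path_to_root(node: Node) -> list[Node]:
        path = []
        while node is not None:
            path.append(node)
            node = node.parent
        return path


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Standard NJ with deterministic tie-breaking and length clamping."""
    n = len(dm.labels)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    bad = dm.undefined_pairs or [
        (dm.labels[i], dm.labels[j])
        for i, j in zip(*np.triu_indices(n, k=1))
        if math.isnan(dm.values[i, j])
    ]
    if bad:
        raise ValueError(
            "undefined distances; prune these pairs first: "
            + ", ".join(f"{a}~{b}" for a, b in bad)
        )

    nodes = [Node(name=l) for l in dm.labels]
    reps = list(dm.labels)  # representative (smallest) leaf label per cluster
    D = dm.values.astype(float).copy()
    active = list(range(n))
    clamp_deficit = 0.0

    if n == 2:
        root = Node()
        for i, node in enumerate(nodes):
            node.length = D[0, 1] / 2.0
            root.add(node)
        return Tree(root)

    while len(active) > 3:
        r = len(active)
        sub = D[np.ix_(active, active)]
        R = sub.sum(axis=1)
        Q = (r - 2) * sub - R[:, None] - R[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cand = np.argwhere(Q <= qmin + 1e-12)
        # deterministic: smallest sorted (rep_i, rep_j)
        best = min(
            (tuple(sorted((reps[active[i]], reps[active[j]]))), i, j)
            for i, j in cand if i < j
        )
        _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = 0.5 * dij + (R[ai] - R[aj]) / (2.0 * (r - 2))
        lj = dij - li
        if li < 0:
            clamp_deficit += -li
            li = 0.0
        if lj < 0:
            clamp_deficit += -lj
            lj = 0.0
        new = Node()
        nodes[i].length, nodes[j].length = li, lj
        new.add(nodes[i])
        new.add(nodes[j])
        # distances to the new node
        newd = 0.5 * (D[i, active] + D[j, active] - dij)
        D[i, active] = newd
        D[active, i] = newd
        D[i, i] = 0.0
        nodes[i] = new
        reps[i] = min(reps[i], reps[j])
        active.remove(j)

    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    root = Node()
    for idx, ln in ((a, la), (b, lb), (c, lc)):
        if ln < 0:
            clamp_deficit += -ln
            ln = 0.0
        nodes[idx].length = ln
        root.add(nodes[idx])
    if clamp_deficit > 0:
        logger.info("NJ clamped negative branch lengths; total deficit %.6g",
                    clamp_deficit)
    return Tree(root)


def bootstrap_support(alignment, B: int = 1000, seed: int = 0) -> Tree:
    """NJ tree of the alignment with column-bootstrap supports on internal edges.

    Replicates whose K2P matrix contains undefined entries are discarded and
    counted; a warning is logged if more than 10% are discarded.
    """
    if len(alignment.records) < 4:
        raise ValueError("need at least 4 rows for bootstrap support")
    if B < 100:
        raise ValueError("B must be >= 100")
    from .evodist import distance_matrix

    labels = [r.id for r in alignment.records]
    codes = encode_rows([r.residues for r in alignment.records])
    tree = neighbor_joining(distance_matrix(alignment))

    rng = np.random.default_rng(seed)
    L = codes.shape[1]
    counts: Counter = Counter()
    discarded = 0
    for _ in range(B):
        cols = rng.integers(0, L, size=L)
        vals = k2p_matrix_from_codes(codes[:, cols])
        if np.isnan(vals).any():
            discarded += 1
            continue
        rep = neighbor_joining(DistanceMatrix(labels, vals))
        counts.update(rep.bipartitions().keys())
    valid = B - discarded
    if discarded > 0.1 * B:
        logger.warning("bootstrap: %d of %d replicates discarded (undefined distances)",
                       discarded, B)
    if valid == 0:
        raise ValueError("all bootstrap replicates had undefined distances")
    for split, node in tree.bipartitions().items():
        node.support = 100.0 * counts[split] / valid
    return tree


def smallest_containing_clade(tree: Tree, ids: Iterable[str],
                              outgroup: Optional[str] = None) -> frozenset:
    """Leaf set of the minimal rooted clade containing all ``ids``.

    The tree is rooted on ``outgroup`` when given, otherwise midpoint-rooted.
    """
    ids = frozenset(ids)
    missing = ids - tree.leaf_names()
    if missing:
        raise KeyError(f"ids not in tree: {sorted(missing)}")
    rooted = root_at_outgroup(tree, outgroup) if outgroup else midpoint_root(tree)
    best: Optional[frozenset] = None
    for node in rooted.root.walk():
        ls = node.leaf_names()
        if ids <= ls and (best is None or len(ls) < len(best)):
            best = ls
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# rerooting


def _adjacency(tree: Tree):
    """Undirected edge map: node -> [(neighbor, length, support)]."""
    adj: dict[int, list] = {}
    obj: dict[int, Node] = {}
    for node in tree.root.walk():
        obj[id(node)] = node
        adj.setdefault(id(node), [])
        for c in node.children:
            adj.setdefault(id(c), [])
            adj[id(node)].append((id(c), c.length, c.support))
            adj[id(c)].append((id(node), c.length, c.support))
    return adj, obj


def _build_rooted(adj, obj, root_edge, frac) -> Tree:
    """Build a new rooted tree with the root inserted on ``root_edge``."""
    u, v, length, support = root_edge
    root = Node()

    # grow u-side and v-side, excluding the split edge
    def grow_side(start: int, other: int, edge_len: float, edge_sup) -> None:
        old = obj[start]
        node = Node(name=old.name, length=edge_len, support=edge_sup)
        root.add(node)
        stack = [(start, other, node)]
        while stack:
            nid, pid, nnode = stack.pop()
            for (mid, ln, sup) in adj[nid]:
                if mid == pid:
                    continue
                child = Node(name=obj[mid].name, length=ln, support=sup)
                nnode.add(child)
                stack.append((mid, nid, child))

    grow_side(u, v, length * frac, support)
    grow_side(v, u, length * (1.0 - frac), support)
    return _suppress_unifurcations(Tree(root))


def _suppress_unifurcations(tree: Tree) -> Tree:
    changed = True
    while changed:
        changed = False
        for node in list(tree.root.walk()):
            if node.is_leaf or node is tree.root:
                continue
            if len(node.children) == 1:
                child = node.children[0]
                child.length += node.length
                if child.support is None:
                    child.support = node.support
                parent = node.parent
                parent.children[parent.children.index(node)] = child
                child.parent = parent
                changed = True
        if len(tree.root.children) == 1:
            only = tree.root.children[0]
            only.parent = None
            only.length = 0.0
            tree.root = only
            changed = True
    return tree


def root_at_outgroup(tree: Tree, outgroup: str) -> Tree:
    """Reroot on the pendant edge of the outgroup leaf (at its midpoint)."""
    leaf = tree.find_leaf(outgroup)
    adj, obj = _adjacency(tree)
    (pid, length, support) = [
        (m, ln, s) for (m, ln, s) in adj[id(leaf)]
    ][0]
    return _build_rooted(adj, obj, (id(leaf), pid, length, support), 0.5)


def midpoint_root(tree: Tree) -> Tree:
    """Root at the midpoint of the longest leaf-to-leaf path."""
    adj, obj = _adjacency(tree)
    leaves = sorted(tree.leaves(), key=lambda n: n.name)
    # single-source path lengths + predecessor maps from each leaf
    best = None  # (dist, a_name, b_name, path)
    for a in leaves:
        dist = {id(a): 0.0}
        prev: dict[int, tuple] = {id(a): None}
        stack = [id(a)]
        while stack:
            nid = stack.pop()
            for (mid, ln, sup) in adj[nid]:
                if mid not in dist:
                    dist[mid] = dist[nid] + ln
                    prev[mid] = (nid, ln, sup)
                    stack.append(mid)
        for b in leaves:
            if b.name <= a.name:
                continue
            key = (-dist[id(b)], a.name, b.name)
            if best is None or key < best[0]:
                best = (key, a, b, dict(prev))
    _, a, b, prev = best
    # walk back from b toward a to find the midpoint edge
    total = -best[0][0]
    target = total / 2.0
    # path b -> a as list of (node, edge_len, edge_sup) steps
    steps = []
    nid = id(b)
    while prev[nid] is not None:
        pid, ln, sup = prev[nid]
        steps.append((nid, pid, ln, sup))
        nid = pid
    acc = 0.0
    for (u, v, ln, sup) in steps:
        if acc + ln >= target - 1e-12:
            frac = (target - acc) / ln if ln > 0 else 0.5
            # u is on b's side; root at frac from u
            return _build_rooted(adj, obj, (u, v, ln, sup), frac)
        acc += ln
    # degenerate (zero-length paths): root on the last edge
    u, v, ln, sup = steps[-1]
    return _build_rooted(adj, obj, (u, v, ln, sup), 0.5)


# ---------------------------------------------------------------------------
# Newick


def to_newick(tree: Tree, support_threshold: float = 0.0) -> str:
    """Serialize with branch lengths; supports below the threshold omitted."""

    def fmt(node: Node) -> str:
        if node.is_leaf:
            return f"{node.name}:{node.length:.10g}"
        inner = ",".join(fmt(c) for c in node.children)
        label = ""
        if node.support is not None and node.support >= support_threshold:
            label = f"{int(round(node.support))}"
        return f"({inner}){label}:{node.length:.10g}"

    root = tree.root
    inner = ",".join(fmt(c) for c in root.children)
    label = ""
    if root.support is not None and root.support >= support_threshold:
        label = f"{int(round(root.support))}"
    return f"({inner}){label};"


def from_newick(text: str) -> Tree:
    """Parse a Newick string with branch lengths and optional support labels."""
    s = text.strip()
    if not s.endswith(";"):
        raise ValueError("newick must end with ';'")
    s = s[:-1]
    pos = 0

    def parse_node() -> Node:
        nonlocal pos
        node = Node()
        if s[pos] == "(":
            pos += 1
            while True:
                node.add(parse_node())
                if s[pos] == ",":
                    pos += 1
                elif s[pos] == ")":
                    pos += 1
                    break
                else:
                    raise ValueError(f"parse error at {pos}: {s[pos:pos+20]!r}")
        # label
        start = pos
        while pos < len(s) and s[pos] not in ",():;":
            pos += 1
        label = s[start:pos]
        if label:
            if node.is_leaf:
                node.name = label
            else:
                node.support = float(label)
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in ",()":
                pos += 1
            node.length = float(s[start:pos])
        return node

    root = parse_node()
    if pos != len(s):
        raise ValueError("trailing characters in newick")
    root.length = 0.0
    return Tree(root)
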