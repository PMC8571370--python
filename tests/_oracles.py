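"""Independent oracles used by the test suite.

These deliberately avoid the package's own algorithms: alignment scores come
from exhaustive path enumeration, K2P values from arbitrary-precision
evaluation, genetic-code facts from Biopython's table 5, additive trees from a
direct construction in plain dictionaries.
"""

from __future__ import annotations

import math
import random


def brute_force_align_score(a: str, b: str, match: float, mismatch: float,
                            gap_open: float, gap_extend: float) -> float:
    """Maximum affine-gap global alignment score by full path enumeration.

    A gap of length k costs gap_open + k * gap_extend. Exponential; only for
    sequences of length <= 8.
    """
    best = -math.inf

    def rec(i: int, j: int, last: str, score: float) -> None:
        nonlocal best
        if i == len(a) and j == len(b):
            if score > best:
                best = score
            return
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            rec(i + 1, j + 1, "M", score + s)
        if i < len(a):
            cost = gap_extend + (0.0 if last == "U" else gap_open)
            rec(i + 1, j, "U", score - cost)
        if j < len(b):
            cost = gap_extend + (0.0 if last == "L" else gap_open)
            rec(i, j + 1, "L", score - cost)

    rec(0, 0, "", 0.0)
    return best


def random_additive_tree(n_taxa: int, rng: random.Random):
    """A random unrooted binary tree with positive branch lengths.

    Returns (labels, dist, splits): the leaf labels, the exact leaf-to-leaf
    path-length matrix as a dict of frozenset pairs, and the set of
    nontrivial bipartitions (canonicalized by the side not containing the
    smallest label).
    """
    labels = [f"T{i:02d}" for i in range(n_taxa)]
    # adjacency with edge lengths; start from a 3-star, attach leaves
    adj: dict[str, dict[str, float]] = {}

    def connect(u, v, w):
        adj.setdefault(u, {})[v] = w
        adj.setdefault(v, {})[u] = w

    def disconnect(u, v):
        del adj[u][v]
        del adj[v][u]

    def elen():
        return round(rng.uniform(0.5, 3.0), 3)

    inner = 0
    if n_taxa == 2:
        connect(labels[0], labels[1], elen())
    else:
        center = "I0"
        inner = 1
        for l in labels[:3]:
            connect(center, l, elen())
        for l in labels[3:]:
            # pick a random existing edge and subdivide it
            edges = [(u, v) for u in adj for v in adj[u] if u < v]
            u, v = rng.choice(edges)
            w = adj[u][v]
            mid = f"I{inner}"
            inner += 1
            disconnect(u, v)
            split = rng.uniform(0.25, 0.75) * w
            connect(u, mid, round(split, 6))
            connect(mid, v, round(w - split, 6))
            connect(mid, l, elen())

    def paths_from(src):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            x = stack.pop()
            for y, w in adj[x].items():
                if y not in dist:
                    dist[y] = dist[x] + w
                    stack.append(y)
        return dist

    dist = {}
    for a in labels:
        d = paths_from(a)
        for b in labels:
            if a < b:
                dist[frozenset((a, b))] = d[b]

    # splits: removing each internal edge partitions the leaves
    splits = set()
    ref = min(labels)
    for u in adj:
        for v in adj[u]:
            if u < v:
                # leaves on u's side without crossing (u,v)
                seen = {u}
                stack = [u]
                while stack:
                    x = stack.pop()
                    for y in adj[x]:
                        if y != v and y not in seen and not (x == u and y == v):
                            if (x, y) == (u, v):
                                continue
                            seen.add(y)
                            stack.append(y)
                side = frozenset(l for l in labels if l in seen)
                if 2 <= len(side) <= n_taxa - 2:
                    canon = side if ref not in side else frozenset(labels) - side
                    splits.add(canon)
    return labels, dist, splits


def biopython_table5():
    """(codon -> amino acid) map from Biopython's invertebrate mito table."""
    from Bio.Data.CodonTable import unambiguous_dna_by_id

    t5 = unambiguous_dna_by_id[5]
    table = dict(t5.forward_table)
    for stop in t5.stop_codons:
        table[stop] = "*"
    return table
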