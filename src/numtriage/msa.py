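"""Pairwise and progressive multiple alignment with affine gap costs.

The aligner is a Gotoh dynamic program over a precomputed column-similarity
matrix, so the same kernel serves sequence-sequence, sequence-profile and
profile-profile alignment. Traceback is deterministic with the preference
diagonal > up (gap in the second input) > left. A one-symbol gap costs
``gap_open + gap_extend``; each further symbol costs ``gap_extend``.

Progressive alignment merges profiles in post-order of an NJ guide tree built
on ``d = 1 - identity`` pairwise distances (terminal gap columns excluded from
identity, since raw reads differ in length for reasons that are not
divergence). De-gapping any output row always reproduces its input residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numba import njit

from .evodist import DistanceMatrix
from .seqio import SequenceRecord

_IDX = {c: i for i, c in enumerate("ACGTN-")}


@dataclass(frozen=True)
class AlignParams:
    match: float = 2.0
    mismatch: float = -1.0
    gap_open: float = 5.0
    gap_extend: float = 2.0

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be >= 0")
        if self.match <= self.mismatch:
            raise ValueError("match score must exceed mismatch score")

    def substitution(self, a: str, b: str) -> float:
        if a in "ACGT" and b in "ACGT":
            return self.match if a == b else self.mismatch
        return 0.0  # N or gap symbols score neutrally


DEFAULT_PARAMS = AlignParams()


@dataclass
class Alignment:
    """Equal-length gapped sequence records."""

    records: list[SequenceRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("alignment needs at least one record")
        L = len(self.records[0].residues)
        if L < 1:
            raise ValueError("zero-length alignment")
        for r in self.records:
            if len(r.residues) != L:
                raise ValueError("rows have unequal lengths")

    @property
    def length(self) -> int:
        return len(self.records[0].residues)

    def row(self, rec_id: str) -> str:
        for r in self.records:
            if r.id == rec_id:
                return r.residues
        raise KeyError(rec_id)

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def take_columns(self, cols) -> "Alignment":
        out = [
            r.with_residues("".join(r.residues[c] for c in cols))
            for r in self.records
        ]
        return Alignment(out, provenance=self.provenance + "|column-subset")


@njit(cache=True)
def _gotoh(sim, gap_open, gap_extend):  # pragma: no cover - exercised via wrapper
    """Affine-gap DP on a similarity matrix; returns score and move path.

    Moves: 0 diagonal, 1 up (consumes a row of input A only), 2 left
    (consumes a column of input B only). Ties prefer diagonal, then up.
    """
    n, m = sim.shape
    NEG = -1e30
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in B (vertical / up)
    Y = np.full((n + 1, m + 1), NEG)  # gap in A (horizontal / left)
    # pointers: 0 from M, 1 from X, 2 from Y
    pM = np.zeros((n + 1, m + 1), dtype=np.int8)
    pX = np.zeros((n + 1, m + 1), dtype=np.int8)
    pY = np.zeros((n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -(gap_open + gap_extend * i)
        pX[i, 0] = 1 if i > 1 else 0
    for j in range(1, m + 1):
        Y[0, j] = -(gap_open + gap_extend * j)
        pY[0, j] = 2 if j > 1 else 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            # M: diagonal
            best, arg = M[i - 1, j - 1], 0
            if X[i - 1, j - 1] > best:
                best, arg = X[i - 1, j - 1], 1
            if Y[i - 1, j - 1] > best:
                best, arg = Y[i - 1, j - 1], 2
            M[i, j] = best + sim[i - 1, j - 1]
            pM[i, j] = arg
            # X: gap in B
            o = M[i - 1, j] - gap_open - gap_extend
            e = X[i - 1, j] - gap_extend
            yv = Y[i - 1, j] - gap_open - gap_extend
            best, arg = o, 0
            if e > best:
                best, arg = e, 1
            if yv > best:
                best, arg = yv, 2
            X[i, j] = best
            pX[i, j] = arg
            # Y: gap in A
            o = M[i, j - 1] - gap_open - gap_extend
            xv = X[i, j - 1] - gap_open - gap_extend
            e = Y[i, j - 1] - gap_extend
            best, arg = o, 0
            if xv > best:
                best, arg = xv, 1
            if e > best:
                best, arg = e, 2
            Y[i, j] = best
            pY[i, j] = arg
    # final state preference: M > X > Y
    score, state = M[n, m], 0
    if X[n, m] > score:
        score, state = X[n, m], 1
    if Y[n, m] > score:
        score, state = Y[n, m], 2
    moves = np.empty(n + m, dtype=np.int8)
    k = 0
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:
            moves[k] = 0
            state = pM[i, j]
            i -= 1
            j -= 1
        elif state == 1:
            moves[k] = 1
            state = pX[i, j]
            i -= 1
        else:
            moves[k] = 2
            state = pY[i, j]
            j -= 1
        k += 1
    return score, moves[:k][::-1].copy()


def _profile_counts(rows: Sequence[str]) -> np.ndarray:
    """Symbol counts per column (6 x L over A,C,G,T,N,-)."""
    L = len(rows[0])
    counts = np.zeros((6, L), dtype=np.float64)
    for row in rows:
        codes = np.frombuffer(row.encode("ascii"), dtype=np.uint8)
        for sym, k in _IDX.items():
            counts[k] += codes == ord(sym)
    return counts


def _column_similarity(ca: np.ndarray, cb: np.ndarray, params: AlignParams) -> np.ndarray:
    """Mean pairwise substitution score between profile columns.

    Only A/C/G/T symbols score; gaps and N contribute zero, and the mean is
    over all row pairs (denominator = n_rows_a * n_rows_b).
    """
    a_bases, b_bases = ca[:4], cb[:4]
    tot_a, tot_b = ca.sum(axis=0)[0], cb.sum(axis=0)[0]
    match_pairs = np.einsum("ki,kj->ij", a_bases, b_bases)
    all_pairs = a_bases.sum(axis=0)[:, None] * b_bases.sum(axis=0)[None, :]
    sim = (params.match * match_pairs + params.mismatch * (all_pairs - match_pairs))
    return sim / (tot_a * tot_b)


def pairwise_align(a: SequenceRecord, b: SequenceRecord,
                   params: AlignParams = DEFAULT_PARAMS) -> tuple[Alignment, float]:
    """Optimal global affine-gap alignment of two ungapped sequences."""
    sa, sb = a.degapped(), b.degapped()
    if not sa or not sb:
        raise ValueError("sequences must be nonempty")
    ca = np.frombuffer(sa.encode("ascii"), dtype=np.uint8)
    cb = np.frombuffer(sb.encode("ascii"), dtype=np.uint8)
    is_base_a = ca != ord("N")
    is_base_b = cb != ord("N")
    eq = ca[:, None] == cb[None, :]
    scorable = is_base_a[:, None] & is_base_b[None, :]
    sim = np.where(eq, params.match, params.mismatch) * scorable
    score, moves = _gotoh(sim, params.gap_open, params.gap_extend)
    ra, rb, i, j = [], [], 0, 0
    for mv in moves:
        if mv == 0:
            ra.append(sa[i]); rb.append(sb[j]); i += 1; j += 1
        elif mv == 1:
            ra.append(sa[i]); rb.append("-"); i += 1
        else:
            ra.append("-"); rb.append(sb[j]); j += 1
    aln = Alignment(
        [a.with_residues("".join(ra)), b.with_residues("".join(rb))],
        provenance="pairwise_align",
    )
    return aln, float(score)


def _pairwise_identity(a: SequenceRecord, b: SequenceRecord,
                       params: AlignParams) -> float:
    """Fraction of identical columns, terminal gap columns excluded."""
    aln, _ = pairwise_align(a, b, params)
    ra, rb = aln.records[0].residues, aln.records[1].residues
    lo, hi = 0, len(ra)
    while lo < hi and (ra[lo] == "-" or rb[lo] == "-"):
        lo += 1
    while hi > lo and (ra[hi - 1] == "-" or rb[hi - 1] == "-"):
        hi -= 1
    cols = hi - lo
    if cols == 0:
        return 0.0
    same = sum(ra[k] == rb[k] for k in range(lo, hi))
    return same / cols


def build_guide_tree(records: Sequence[SequenceRecord],
                     params: AlignParams = DEFAULT_PARAMS):
    """NJ guide tree on 1 - identity distances from pairwise alignments."""
    from .phylo import Tree, neighbor_joining

    if len(records) < 2:
        raise ValueError("need at least 2 records")
    n = len(records)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = 1.0 - _pairwise_identity(records[i], records[j], params)
    return neighbor_joining(DistanceMatrix([r.id for r in records], D))


def _merge(rows_a: list[str], rows_b: list[str], params: AlignParams
           ) -> tuple[list[str], list[str]]:
    ca, cb = _profile_counts(rows_a), _profile_counts(rows_b)
    sim = _column_similarity(ca, cb, params)
    _, moves = _gotoh(sim, params.gap_open, params.gap_extend)
    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    i = j = 0
    for mv in moves:
        if mv == 0:
            for k, row in enumerate(rows_a):
                out_a[k].append(row[i])
            for k, row in enumerate(rows_b):
                out_b[k].append(row[j])
            i += 1; j += 1
        elif mv == 1:
            for k, row in enumerate(rows_a):
                out_a[k].append(row[i])
            for k in range(len(rows_b)):
                out_b[k].append("-")
            i += 1
        else:
            for k in range(len(rows_a)):
                out_a[k].append("-")
            for k, row in enumerate(rows_b):
                out_b[k].append(row[j])
            j += 1
    return ["".join(r) for r in out_a], ["".join(r) for r in out_b]


def progressive_align(records: Sequence[SequenceRecord],
                      params: AlignParams = DEFAULT_PARAMS) -> Alignment:
    """Progressive multiple alignment along an NJ guide tree.

    Row order in the result matches the input order; gap-only columns are
    never produced (every output column consumes at least one profile column).
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate record ids")
    by_id = {r.id: r for r in records}
    if len(records) == 2:
        aln, _ = pairwise_align(records[0], records[1], params)
        return Alignment(list(aln.records), provenance="progressive_align(n=2)")

    guide = build_guide_tree(records, params)

    def merge_node(node) -> tuple[list[str], list[str]]:
        """Post-order merge; returns (ids, gapped rows)."""
        if node.is_leaf:
            return [node.name], [by_id[node.name].degapped()]
        child_profiles = [merge_node(c) for c in node.children]
        ids_acc, rows_acc = child_profiles[0]
        for ids_b, rows_b in child_profiles[1:]:
            rows_acc, rows_b = _merge(rows_acc, rows_b, params)
            ids_acc = ids_acc + ids_b
            rows_acc = rows_acc + rows_b
        return ids_acc, rows_acc

    out_ids, out_rows = merge_node(guide.root)
    row_of = dict(zip(out_ids, out_rows))
    recs = [by_id[i].with_residues(row_of[i]) for i in ids]
    return Alignment(recs, provenance=f"progressive_align(n={len(records)})")


def trim_to_window(alignment: Alignment, anchor_ids: Sequence[str]) -> Alignment:
    """Trim all rows to the non-gap span of the shortest anchor row.

    The anchor is the row (among ``anchor_ids``) with the fewest non-gap
    symbols; columns before its first and after its last non-gap column are
    removed from every row. Idempotent.
    """
    ids = set(alignment.ids())
    unknown = [a for a in anchor_ids if a not in ids]
    if unknown:
        raise KeyError(f"anchor ids not in alignment: {unknown}")
    if not anchor_ids:
        raise ValueError("need at least one anchor id")
    anchor = min(
        anchor_ids,
        key=lambda a: (sum(c != "-" for c in alignment.row(a)), a),
    )
    row = alignment.row(anchor)
    nz = [k for k, c in enumerate(row) if c != "-"]
    if not nz:
        raise ValueError(f"anchor row {anchor!r} is all gaps")
    lo, hi = nz[0], nz[-1] + 1
    recs = [r.with_residues(r.residues[lo:hi]) for r in alignment.records]
    return Alignment(recs, provenance=alignment.provenance + f"|trimmed[{lo}:{hi}]")
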