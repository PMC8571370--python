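"""Pairwise site classification and Kimura two-parameter distances.

Distances follow MEGA's "pairwise deletion" semantics: for each sequence pair,
alignment columns with a gap or an N in either row are excluded before the
transition proportion P and transversion proportion Q are formed, and

    K = -1/2 * ln[(1 - 2P - Q) * sqrt(1 - 2Q)]

When the argument of either log term is non-positive (saturation) the distance
is undefined; undefined pairs are flagged and carried as NaN sentinels, never
silently dropped. Standard errors of mean distances are obtained by column
bootstrap (resampling alignment columns with replacement).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np

# symbol codes: A,C,G,T = 0..3, N = 4, gap = 5
_CODE = np.full(128, 4, dtype=np.int8)
for i, c in enumerate("ACGT"):
    _CODE[ord(c)] = i
_CODE[ord("N")] = 4
_CODE[ord("-")] = 5


def encode_rows(rows: Iterable[str]) -> np.ndarray:
    """Encode gapped rows as an int8 matrix (A,C,G,T=0..3, N=4, '-'=5)."""
    mat = np.vstack(
        [_CODE[np.frombuffer(r.encode("ascii"), dtype=np.uint8)] for r in rows]
    )
    return mat


@dataclass(frozen=True)
class SiteDiffSummary:
    """Per-pair column tallies feeding K2P and the difference thresholds."""

    compared_sites: int  # columns where both rows have A/C/G/T
    transitions: int  # A<->G, C<->T
    transversions: int
    indel_columns: int  # columns where exactly one row is gapped
    indel_events: int  # maximal single-row gap runs
    n_ambiguous: int = 0  # columns excluded because either row has N

    def __post_init__(self) -> None:
        if min(self.compared_sites, self.transitions, self.transversions,
               self.indel_columns, self.indel_events) < 0:
            raise ValueError("negative count")
        if self.transitions + self.transversions > self.compared_sites:
            raise ValueError("mismatches exceed compared sites")

    @property
    def mismatch_columns(self) -> int:
        return self.transitions + self.transversions

    @property
    def P(self) -> float:
        return self.transitions / self.compared_sites if self.compared_sites else math.nan

    @property
    def Q(self) -> float:
        return self.transversions / self.compared_sites if self.compared_sites else math.nan


def classify_columns(a: str, b: str) -> SiteDiffSummary:
    """Classify aligned columns of two equal-length gapped rows.

    Columns with N in either row contribute only to ``n_ambiguous``; gap-gap
    columns are ignored entirely. Transitions are purine-purine or
    pyrimidine-pyrimidine mismatches.
    """
    if len(a) != len(b):
        raise ValueError(f"row lengths differ: {len(a)} vs {len(b)}")
    x, y = encode_rows([a, b])
    has_n = (x == 4) | (y == 4)
    xg, yg = x == 5, y == 5
    both_base = (x < 4) & (y < 4) & ~has_n
    diff = both_base & (x != y)
    ts = diff & (((x ^ y) & 1) == 0)  # same parity => A<->G or C<->T
    one_gap = (xg ^ yg) & ~has_n

    # indel events: maximal runs of one-gap columns with the same row gapped;
    # gap-gap and N columns do not interrupt a run, other columns do.
    events = 0
    state = 0  # 0 none, 1 a gapped, 2 b gapped
    for i in range(len(x)):
        if has_n[i] or (xg[i] and yg[i]):
            continue
        if xg[i]:
            if state != 1:
                events += 1
            state = 1
        elif yg[i]:
            if state != 2:
                events += 1
            state = 2
        else:
            state = 0

    return SiteDiffSummary(
        compared_sites=int(both_base.sum()),
        transitions=int(ts.sum()),
        transversions=int(diff.sum() - ts.sum()),
        indel_columns=int(one_gap.sum()),
        indel_events=events,
        n_ambiguous=int((has_n & ~(xg & yg)).sum()),
    )


class K2PResult(NamedTuple):
    value: float  # substitutions/site; NaN when undefined
    defined: bool
    reason: str = ""


def k2p_distance(s: SiteDiffSummary) -> K2PResult:
    """Kimura two-parameter distance from a site summary (pairwise deletion)."""
    if s.compared_sites == 0:
        return K2PResult(math.nan, False, "no comparable sites")
    P, Q = s.P, s.Q
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return K2PResult(math.nan, False, f"saturated (P={P:.4f}, Q={Q:.4f})")
    return K2PResult(-0.5 * math.log(w1 * math.sqrt(w2)), True)


def difference_count(a: str, b: str, mode: str = "events") -> int:
    """Nucleotide differences between two aligned rows, indels included.

    mode="events" counts a contiguous gap run as one difference (mutational
    events); mode="columns" counts every indel column.
    """
    s = classify_columns(a, b)
    if mode == "events":
        return s.mismatch_columns + s.indel_events
    if mode == "columns":
        return s.mismatch_columns + s.indel_columns
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class DistanceMatrix:
    """Symmetric K2P distance matrix with NaN sentinels for undefined pairs."""

    labels: list[str]
    values: np.ndarray
    undefined_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("label count does not match matrix dimension")
        if not np.allclose(np.nan_to_num(self.values), np.nan_to_num(self.values.T)):
            raise ValueError("matrix not symmetric")
        if not np.all(np.diag(self.values) == 0):
            raise ValueError("nonzero diagonal")

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.index(a), self.index(b)])

    def submatrix(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.index(l) for l in labels]
        vals = self.values[np.ix_(idx, idx)]
        und = [
            (a, b) for a, b in self.undefined_pairs if a in set(labels) and b in set(labels)
        ]
        return DistanceMatrix(list(labels), vals, und)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for i, lab in enumerate(self.labels):
                cells = [
                    "NA" if math.isnan(v) else f"{v:.8f}" for v in self.values[i]
                ]
                fh.write(lab + "\t" + "\t".join(cells) + "\n")


def k2p_matrix_from_codes(codes: np.ndarray) -> np.ndarray:
    """All-pairs K2P on an encoded alignment matrix; NaN marks undefined."""
    n = codes.shape[0]
    out = np.zeros((n, n), dtype=float)
    if n < 2:
        return out
    iu, ju = np.triu_indices(n, k=1)
    A, B = codes[iu], codes[ju]
    valid = (A < 4) & (B < 4)
    L = valid.sum(axis=1).astype(float)
    diff = valid & (A != B)
    ts = diff & (((A ^ B) & 1) == 0)
    nP = ts.sum(axis=1)
    nQ = diff.sum(axis=1) - nP
    with np.errstate(divide="ignore", invalid="ignore"):
        P = np.where(L > 0, nP / L, np.nan)
        Q = np.where(L > 0, nQ / L, np.nan)
        w1 = 1.0 - 2.0 * P - Q
        w2 = 1.0 - 2.0 * Q
        d = np.where((w1 > 0) & (w2 > 0), -0.5 * np.log(w1 * np.sqrt(np.abs(w2))), np.nan)
    out[iu, ju] = d
    out[ju, iu] = d
    return out


def distance_matrix(alignment) -> DistanceMatrix:
    """Pairwise K2P distances for all rows of an alignment."""
    rows = [r.residues for r in alignment.records]
    if len(rows) < 2:
        raise ValueError("need at least 2 rows")
    labels = [r.id for r in alignment.records]
    vals = k2p_matrix_from_codes(encode_rows(rows))
    und = [
        (labels[i], labels[j])
        for i, j in zip(*np.triu_indices(len(labels), k=1))
        if math.isnan(vals[i, j])
    ]
    return DistanceMatrix(labels, vals, und)


def mean_distance_with_se(
    alignment,
    labels: Sequence[str],
    B: int = 1000,
    seed: int = 0,
    labels2: Optional[Sequence[str]] = None,
) -> tuple[float, float]:
    """Mean pairwise K2P over a label set, with column-bootstrap SE.

    With ``labels2`` the mean is over cross pairs (one id from each set),
    as used for between-group divergence summaries. Undefined pairs are
    excluded from every mean. SE is the standard deviation of the mean across
    ``B`` column resamples of the alignment.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    id2row = {r.id: r.residues for r in alignment.records}
    if labels2 is None:
        if len(labels) < 2:
            raise ValueError("need at least 2 labels")
        rows = [id2row[l] for l in labels]
        codes = encode_rows(rows)
        pair_idx = None  # within-set: all pairs
    else:
        rows = [id2row[l] for l in list(labels) + list(labels2)]
        codes = encode_rows(rows)
        n1 = len(labels)
        pair_idx = [(i, n1 + j) for i in range(n1) for j in range(len(labels2))]

    def _mean(c: np.ndarray) -> float:
        m = k2p_matrix_from_codes(c)
        if pair_idx is None:
            iu, ju = np.triu_indices(len(rows), k=1)
            vals = m[iu, ju]
        else:
            vals = np.array([m[i, j] for i, j in pair_idx])
        vals = vals[~np.isnan(vals)]
        return float(vals.mean()) if vals.size else math.nan

    point = _mean(codes)
    rng = np.random.default_rng(seed)
    L = codes.shape[1]
    reps = np.empty(B)
    for b in range(B):
        cols = rng.integers(0, L, size=L)
        reps[b] = _mean(codes[:, cols])
    reps = reps[~np.isnan(reps)]
    se = float(reps.std(ddof=1)) if reps.size > 1 else math.nan
    return point, se
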