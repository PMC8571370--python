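"""Synthetic haplotype mixtures demonstrating the multi-peak mechanism.

``shared_peak_mixture`` builds a synthetic alignment of one genuine haplotype
plus nine NUMT haplotypes in which subsets of the NUMTs share the same
alternative nucleotide at chosen sites — the configuration that produces
double and triple peaks in a direct-sequencing electropherogram. It is a
constructed stand-in for a real trace window: the published deposited clone
sequences are not bundled, so the sharing pattern (counts of double- and
triple-peak sites) is imposed by construction.
"""

from __future__ import annotations

import numpy as np

from .msa import Alignment
from .seqio import SequenceRecord

_ALT = {"A": ("G", "C"), "C": ("T", "G"), "G": ("A", "T"), "T": ("C", "A")}


def shared_peak_mixture(n_double: int = 7, n_triple: int = 5,
                        n_numts: int = 9, length: int = 60, seed: int = 0,
                        genuine_weight: float = 0.28
                        ) -> tuple[Alignment, list[float]]:
    """A 1-genuine + ``n_numts``-NUMT alignment with a fixed sharing pattern.

    At ``n_double`` sites three NUMTs share one alternative base (two peaks:
    genuine + shared alternative); at ``n_triple`` sites two disjoint NUMT
    trios share two different alternatives (three peaks). Weights are the
    genuine fraction plus equal NUMT fractions summing to the remainder.

    Returns the alignment and the per-row weight vector (genuine row first).
    """
    if n_numts < 6:
        raise ValueError("need at least 6 NUMT rows for the triple-peak trios")
    if n_double + n_triple > length:
        raise ValueError("more multi-peak sites than columns")
    rng = np.random.default_rng(seed)
    genuine = rng.choice(list("ACGT"), size=length)
    rows = [genuine.copy() for _ in range(n_numts)]
    sites = rng.choice(length, size=n_double + n_triple, replace=False)
    for k in range(n_double):
        col = sites[k]
        alt = _ALT[genuine[col]][0]
        for r in rows[:3]:
            r[col] = alt
    for k in range(n_triple):
        col = sites[n_double + k]
        alt1, alt2 = _ALT[genuine[col]]
        for r in rows[:3]:
            r[col] = alt1
        for r in rows[3:6]:
            r[col] = alt2
    records = [SequenceRecord("genuine", "".join(genuine), role="simulated")]
    records += [
        SequenceRecord(f"numt{i + 1}", "".join(r), role="simulated")
        for i, r in enumerate(rows)
    ]
    numt_w = (1.0 - genuine_weight) / n_numts
    weights = [genuine_weight] + [numt_w] * n_numts
    return Alignment(records, provenance="synthetic shared-peak mixture"), weights
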