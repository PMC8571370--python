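"""Predicted Sanger peak multiplicity from a mixture of co-amplified templates.

Direct sequencing of a PCR product reads the weighted sum of every template
that amplified: at each position the signal of a nucleotide is proportional to
the summed copy fraction of the haplotypes carrying it. Where several
pseudogene copies share the same alternative base, their weights add up and a
secondary peak emerges; where a minority template carries a gap, the
frame-slipped signal disrupts the trace downstream. The model here is linear
in template fraction with a flat detection threshold — the mechanism is about
shared-nucleotide weight, not instrument physics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .msa import Alignment


@dataclass(frozen=True)
class SiteSignal:
    column: int
    peaks: tuple[tuple[str, float], ...]  # (nucleotide, summed weight), desc.
    gap_disrupted: bool

    @property
    def multiplicity(self) -> int:
        return len(self.peaks)


@dataclass
class PeakProfile:
    sites: list[SiteSignal]
    threshold: float

    def __len__(self) -> int:
        return len(self.sites)


def predict_site_signals(alignment: Alignment, weights: Sequence[float],
                         threshold: float = 0.10) -> PeakProfile:
    """Per-column peak sets from normalized row weights.

    Nucleotides whose summed weight reaches the detection threshold form the
    peak set of a column. A column where gapped rows carry at least the
    threshold weight is flagged gap-disrupted.
    """
    rows = [r.residues for r in alignment.records]
    if len(weights) != len(rows):
        raise ValueError(
            f"weights ({len(weights)}) do not match rows ({len(rows)})"
        )
    w = np.asarray(weights, dtype=float)
    if (w < 0).any():
        raise ValueError("weights must be nonnegative")
    if abs(w.sum() - 1.0) > 1e-6:
        raise ValueError("weights must be normalized to sum 1")
    if not 0.0 < threshold <= 0.5:
        raise ValueError("threshold must lie in (0, 0.5]")

    sites = []
    for col in range(alignment.length):
        acc: dict[str, float] = {}
        gap_w = 0.0
        for row, wi in zip(rows, w):
            c = row[col]
            if c == "-":
                gap_w += wi
            elif c in "ACGT":
                acc[c] = acc.get(c, 0.0) + wi
        peaks = tuple(
            sorted(
                ((nuc, wt) for nuc, wt in acc.items() if wt >= threshold),
                key=lambda p: (-p[1], p[0]),
            )
        )
        sites.append(
            SiteSignal(column=col, peaks=peaks, gap_disrupted=gap_w >= threshold)
        )
    return PeakProfile(sites=sites, threshold=threshold)


def multipeak_counts(profile: PeakProfile) -> tuple[int, int, int]:
    """(columns with exactly 2 peaks, exactly 3 peaks, gap-disrupted columns)."""
    n2 = sum(s.multiplicity == 2 for s in profile.sites)
    n3 = sum(s.multiplicity == 3 for s in profile.sites)
    ng = sum(s.gap_disrupted for s in profile.sites)
    return n2, n3, ng


def call_strongest(profile: PeakProfile, alignment: Alignment,
                   weights: Sequence[float]) -> str:
    """The base-called sequence: per column the maximum-weight nucleotide.

    Weight ties are broken toward the base of the highest-weight single row,
    then alphabetically. Columns with no above-threshold peak (all signal on
    gaps) are called '-'.
    """
    rows = [r.residues for r in alignment.records]
    w = list(map(float, weights))
    order = sorted(range(len(rows)), key=lambda i: (-w[i], i))
    called = []
    for s in profile.sites:
        if not s.peaks:
            called.append("-")
            continue
        top = max(p[1] for p in s.peaks)
        cands = sorted(nuc for nuc, wt in s.peaks if wt >= top - 1e-12)
        if len(cands) > 1:
            for i in order:
                c = rows[i][s.column]
                if c in cands:
                    cands = [c]
                    break
            cands = [cands[0]] if isinstance(cands, list) else [cands]
        called.append(cands[0])
    return "".join(called)


def profile_to_tsv(profile: PeakProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write("column\tmultiplicity\tpeaks\tgap_disrupted\n")
        for s in profile.sites:
            peaks = ",".join(f"{n}:{w:.3f}" for n, w in s.peaks)
            fh.write(f"{s.column}\t{s.multiplicity}\t{peaks}\t{int(s.gap_disrupted)}\n")
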