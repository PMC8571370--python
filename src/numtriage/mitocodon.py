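"""Codon diagnostics under the invertebrate mitochondrial genetic code.

COI is protein coding, so pseudogene copies betray themselves through
premature stop codons, frameshifting indels and an excess of nonsynonymous
change, while authentic mitochondrial variation is dominated by synonymous
third-position transitions. This module translates fragments under NCBI
translation table 5 (ATA=Met, TGA=Trp, AGA/AGG=Ser; stops TAA and TAG only),
infers the reading frame of a fragment as the frame minimizing internal stops,
and annotates each substitution between a genuine haplotype and a clone with
its codon position, synonymous status and transition status.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

_BASES = "TCAG"
# NCBI translation table 5 (invertebrate mitochondrial), codons in TCAG order
_AAS = "FFLLSSSSYY**CCWWLLLLPPPPHHQQRRRRIIMMTTTTNNKKSSSSVVVVAAAADDEEGGGG"

TABLE5: dict[str, str] = {
    a + b + c: _AAS[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}
STOP_CODONS = frozenset(c for c, aa in TABLE5.items() if aa == "*")


def translate_codon(codon: str) -> str:
    """One codon to one amino acid; '*' for stop, 'X' if N or gap present."""
    if len(codon) != 3:
        raise ValueError(f"codon must have length 3, got {codon!r}")
    if set(codon) - set("ACGT"):
        return "X"
    return TABLE5[codon]


def translate_mito(seq: str, frame: int = 0) -> str:
    """Translate an ungapped fragment under table 5 from the given frame.

    The trailing partial codon is ignored; codons containing N become 'X'.
    """
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1 or 2")
    if "-" in seq:
        raise ValueError("translate_mito expects an ungapped sequence")
    if len(seq) < frame + 3:
        raise ValueError("sequence too short for this frame")
    aa = []
    for i in range(frame, len(seq) - 2, 3):
        aa.append(translate_codon(seq[i : i + 3]))
    return "".join(aa)


@dataclass(frozen=True)
class FrameCall:
    frame: int
    stop_counts: tuple[int, int, int]
    pseudogene_like: bool  # every frame contains at least one stop

    @property
    def stops_in_frame(self) -> int:
        return self.stop_counts[self.frame]


def infer_frame(seq: str) -> FrameCall:
    """Choose the reading frame with the fewest stop codons.

    Ties go to the smallest offset. When every frame has a stop, the fragment
    is flagged pseudogene-like.
    """
    if len(seq.replace("-", "")) < 30:
        raise ValueError("need at least 30 nt to infer a frame")
    s = seq.replace("-", "")
    counts = tuple(translate_mito(s, f).count("*") for f in (0, 1, 2))
    frame = counts.index(min(counts))
    return FrameCall(frame=frame, stop_counts=counts,
                     pseudogene_like=min(counts) > 0)


@dataclass(frozen=True)
class SubstitutionRecord:
    column: int  # alignment column index
    codon_position: int  # 1, 2 or 3 on the reference row's frame
    synonymous: bool
    transition: bool
    ref_base: str
    alt_base: str


@dataclass
class CodonAnnotation:
    """Codon-level comparison of a clone row against the genuine row."""

    frame: int
    stop_positions: list[int]  # codon indices with a stop in the clone
    aa_length: int
    substitutions: list[SubstitutionRecord]
    aa_differences: int
    frameshift: bool  # clone carries a gap run of length not divisible by 3

    @property
    def nonsynonymous_count(self) -> int:
        return sum(not s.synonymous for s in self.substitutions)

    @property
    def stop_count(self) -> int:
        return len(self.stop_positions)


def _gap_runs(row: str) -> list[int]:
    runs, n = [], 0
    for c in row:
        if c == "-":
            n += 1
        elif n:
            runs.append(n)
            n = 0
    if n:
        runs.append(n)
    return runs


def annotate_substitutions(ref_row: str, clone_row: str, frame: int = 0
                           ) -> CodonAnnotation:
    """Annotate substitutions of an aligned (reference, clone) row pair.

    Codon positions are defined on the reference row's ungapped coordinates;
    clone indels never re-frame the reference. A gap run whose length is not a
    multiple of 3 in either row marks a frameshift: clone translation beyond it
    is unreliable, and amino-acid differences are then counted only up to the
    first frameshifting indel column.
    """
    if len(ref_row) != len(clone_row):
        raise ValueError("rows must have equal length")
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1 or 2")

    ref_ungapped = ref_row.replace("-", "")
    subs: list[SubstitutionRecord] = []
    ref_pos = -1  # ungapped position on reference
    first_fs_col: Optional[int] = None

    # locate frameshifting gap runs (either row) by alignment column
    col = 0
    run_len, run_start = 0, 0
    for k in range(len(ref_row) + 1):
        gap_here = k < len(ref_row) and (ref_row[k] == "-") != (clone_row[k] == "-")
        if gap_here:
            if run_len == 0:
                run_start = k
            run_len += 1
        else:
            if run_len and run_len % 3 != 0 and first_fs_col is None:
                first_fs_col = run_start
            run_len = 0

    for k, (a, b) in enumerate(zip(ref_row, clone_row)):
        if a != "-":
            ref_pos += 1
        if a in "ACGT" and b in "ACGT" and a != b:
            if ref_pos < frame:
                continue
            cpos = (ref_pos - frame) % 3 + 1
            codon_start = ref_pos - (cpos - 1)
            if codon_start + 3 > len(ref_ungapped):
                continue  # trailing partial codon
            ref_codon = ref_ungapped[codon_start : codon_start + 3]
            alt_codon = (
                ref_codon[: cpos - 1] + b + ref_codon[cpos:]
            )
            subs.append(
                SubstitutionRecord(
                    column=k,
                    codon_position=cpos,
                    synonymous=translate_codon(ref_codon) == translate_codon(alt_codon),
                    transition=(a + b) in ("AG", "GA", "CT", "TC"),
                    ref_base=a,
                    alt_base=b,
                )
            )

    clone_ungapped = clone_row.replace("-", "")
    frameshift = first_fs_col is not None

    # clone translation in its own induced frame (same frame offset relative
    # to the aligned start), for stop scanning
    clone_aa = (
        translate_mito(clone_ungapped, frame)
        if len(clone_ungapped) >= frame + 3
        else ""
    )
    stop_positions = [i for i, aa in enumerate(clone_aa) if aa == "*"]

    # amino-acid differences over the co-translatable span
    ref_aa = translate_mito(ref_ungapped, frame) if len(ref_ungapped) >= frame + 3 else ""
    if frameshift:
        # only codons fully before the first frameshifting column count
        ref_before = sum(1 for k in range(first_fs_col) if ref_row[k] != "-")
        n_codons = max(0, (ref_before - frame) // 3)
        aa_diff = sum(
            x != y for x, y in zip(ref_aa[:n_codons], clone_aa[:n_codons])
        )
    else:
        aa_diff = sum(x != y for x, y in zip(ref_aa, clone_aa))

    return CodonAnnotation(
        frame=frame,
        stop_positions=stop_positions,
        aa_length=len(clone_aa),
        substitutions=subs,
        aa_differences=aa_diff,
        frameshift=frameshift,
    )
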