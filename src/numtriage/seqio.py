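"""Sequence records, FASTA input/output and in-silico PCR.

The unit of data everywhere in this package is a :class:`SequenceRecord`: one
nucleotide sequence together with the metadata the triage pipeline needs (which
mtDNA region it comes from, which individual, and whether it is a direct-
sequencing read, a clone, a determined genuine haplotype, a reference
mitogenome or a simulated sequence).

``find_amplicon`` locates a primer-bounded PCR product on a template (linear or
circular) by ungapped Hamming matching of the forward primer on the plus strand
and of the reverse-complemented reverse primer downstream, mirroring how
amplicon sizes are predicted from a reference mitogenome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALLOWED = set("ACGTN-")
REGIONS = ("COI", "12S", "Dloop", "other")
ROLES = ("direct", "clone", "genuine", "reference", "simulated")

_COMP = str.maketrans("ACGTN-", "TGCAN-")


def reverse_complement(residues: str) -> str:
    """Reverse complement over the alphabet {A,C,G,T,N,-}."""
    return residues.translate(_COMP)[::-1]


@dataclass
class SequenceRecord:
    """One nucleotide sequence with identity and role metadata.

    ``residues`` are upper-case symbols over {A,C,G,T,N,-}; gaps only appear in
    aligned records.
    """

    id: str
    residues: str
    description: str = ""
    region: str = "other"
    individual: str = ""
    role: str = "clone"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be nonempty")
        if not self.residues:
            raise ValueError(f"record {self.id!r}: residues must be nonempty")
        bad = set(self.residues) - ALLOWED
        if bad:
            pos = next(i for i, c in enumerate(self.residues) if c in bad)
            raise ValueError(
                f"record {self.id!r}: illegal symbol {self.residues[pos]!r} "
                f"at position {pos}"
            )
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")

    def degapped(self) -> str:
        return self.residues.replace("-", "")

    def with_residues(self, residues: str) -> "SequenceRecord":
        return replace(self, residues=residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse primer pair, both written 5'->3' on their own strand."""

    forward: str
    reverse: str
    name: str = ""

    def __post_init__(self) -> None:
        for label, p in (("forward", self.forward), ("reverse", self.reverse)):
            if not p:
                raise ValueError(f"{label} primer must be nonempty")
            if set(p) - set("ACGT"):
                raise ValueError(f"{label} primer has symbols outside ACGT: {p}")
            if not 15 <= len(p) <= 30:
                raise ValueError(f"{label} primer length {len(p)} outside 15-30")


#: The six amplification primers for the three mtDNA regions of the Japanese
#: spiny lobster (COI, 12S rDNA, control region).
DEFAULT_PRIMERS = {
    "COI": PrimerPair("ACGCAACGATGATTTTTCTCTAC", "ACAGCAATAATTATGGTTGCCG", "PanJCOI"),
    "12S": PrimerPair("TTAATGAAAGCGACGGGCAA", "CCTATAGTTTGATTCTTGCTA", "PanJ12S"),
    "Dloop": PrimerPair("TAGCAAGAATCAAACTATAG", "ACATTACTTGCTCTATCAAA", "PanJDloop"),
}

#: Expected full product sizes (including both primer footprints) on the
#: reference mitogenome, per region.
EXPECTED_PRODUCT_SIZE = {"COI": 935, "12S": 802, "Dloop": 863}


def _normalize(seq: str, source: str) -> str:
    s = seq.upper().replace("U", "T")
    bad = set(s) - ALLOWED
    if bad:
        pos = next(i for i, c in enumerate(s) if c in bad)
        raise ValueError(f"{source}: illegal symbol {s[pos]!r} at offset {pos}")
    return s


def read_fasta(path, region: str = "other", role: str = "clone") -> list[SequenceRecord]:
    """Read a FASTA file into validated :class:`SequenceRecord` objects.

    The id is the first whitespace-delimited header token; the full header is
    kept as the description. Lowercase is upcased and U is mapped to T.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: dict[str, int] = {}
    for entry in SeqIO.parse(str(path), "fasta"):
        residues = _normalize(str(entry.seq), f"{path.name}:{entry.id}")
        records.append(
            SequenceRecord(
                id=entry.id,
                residues=residues,
                description=entry.description,
                region=region,
                role=role,
            )
        )
        seen[entry.id] = seen.get(entry.id, 0) + 1
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    dups = sorted(i for i, n in seen.items() if n > 1)
    if dups:
        raise ValueError(f"{path}: duplicate ids: {', '.join(dups)}")
    return records


def write_fasta(records: Sequence[SequenceRecord], path, width: int = 70) -> Path:
    """Write records as wrapped FASTA; round-trip safe for ids and residues."""
    if not records:
        raise ValueError("cannot write an empty record collection")
    if width < 1:
        raise ValueError("width must be positive")
    path = Path(path)
    bio = [
        SeqRecord(Seq(r.residues), id=r.id, description=r.description or "")
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)
    return path


def _encode(s: str) -> np.ndarray:
    return np.frombuffer(s.encode("ascii"), dtype=np.uint8)


def _hamming_hits(template: str, probe: str, max_mismatch: int) -> np.ndarray:
    """Start positions where probe matches template within max_mismatch.

    Ungapped comparison; N (or any non-identical symbol) counts as a mismatch.
    """
    t, p = _encode(template), _encode(probe)
    if len(t) < len(p):
        return np.empty(0, dtype=int)
    windows = np.lib.stride_tricks.sliding_window_view(t, len(p))
    mism = (windows != p).sum(axis=1)
    return np.nonzero(mism <= max_mismatch)[0]


@dataclass(frozen=True)
class AmpliconHit:
    """A primer-bounded product: [start, end) on the template plus strand."""

    start: int
    end: int
    product: SequenceRecord


class NoAmpliconError(ValueError):
    pass


class MultipleAmpliconsError(ValueError):
    def __init__(self, candidates):
        self.candidates = candidates
        super().__init__(
            "multiple candidate products: "
            + ", ".join(f"[{s}, {e})" for s, e in candidates)
        )


def find_amplicon(
    template: SequenceRecord,
    primers: PrimerPair,
    max_mismatch: int = 0,
    circular: bool = False,
) -> AmpliconHit:
    """Locate the unique PCR product bounded by a primer pair.

    The product includes both primer footprints: it runs from the 5' end of the
    forward-primer match through the last base of the reverse-primer footprint
    (the reverse primer is matched as its reverse complement on the plus
    strand). Circular templates are searched across the origin; coordinates are
    reported modulo the template length and the product may wrap.
    """
    seq = template.degapped()
    L = len(seq)
    search = seq + seq[: L - 1] if circular else seq
    rc_rev = reverse_complement(primers.reverse)

    f_hits = _hamming_hits(search, primers.forward, max_mismatch)
    r_hits = _hamming_hits(search, rc_rev, max_mismatch)
    if circular:
        f_hits = f_hits[f_hits < L]

    candidates: list[tuple[int, int]] = []
    for f in f_hits:
        for r in r_hits:
            end = int(r) + len(rc_rev)
            if r >= f + len(primers.forward) and end - f <= L:
                candidates.append((int(f), end))
    # keep only the shortest product per forward site (PCR yields the
    # proximal product)
    best: dict[int, tuple[int, int]] = {}
    for f, e in candidates:
        if f not in best or e < best[f][1]:
            best[f] = (f, e)
    candidates = sorted(best.values())
    if not candidates:
        raise NoAmpliconError(
            f"no amplicon for primers {primers.name or '(unnamed)'} on "
            f"{template.id} within {max_mismatch} mismatches"
        )
    if len(candidates) > 1:
        raise MultipleAmpliconsError(candidates)
    start, end = candidates[0]
    product = SequenceRecord(
        id=f"{template.id}|amplicon",
        residues=search[start:end],
        description=f"product [{start},{end}) of {primers.name or 'primers'}",
        region=template.region,
        individual=template.individual,
        role=template.role,
    )
    return AmpliconHit(start=start % L, end=end % L if circular else end, product=product)


def trim_primers(
    record: SequenceRecord,
    primers: PrimerPair,
    max_mismatch: int = 2,
    strict: bool = False,
) -> SequenceRecord:
    """Remove the two primer footprints from an amplicon sequence.

    The forward footprint is looked for at the 5' end and the reverse-
    complemented reverse primer at the 3' end, each within ``max_mismatch``
    Hamming mismatches. With ``strict`` a missing footprint is an error;
    otherwise the record is returned with a warning for each missing end.
    """
    seq = record.degapped()
    f, r = primers.forward, reverse_complement(primers.reverse)
    lo, hi = 0, len(seq)
    missing = []
    if len(seq) >= len(f) and _hamming_count(seq[: len(f)], f) <= max_mismatch:
        lo = len(f)
    else:
        missing.append("forward")
    if len(seq) - lo >= len(r) and _hamming_count(seq[-len(r):], r) <= max_mismatch:
        hi = len(seq) - len(r)
    else:
        missing.append("reverse")
    if missing:
        msg = f"record {record.id}: {' and '.join(missing)} primer footprint not found"
        if strict:
            raise ValueError(msg)
        warnings.warn(msg)
    if lo == 0 and hi == len(seq):
        return record
    return record.with_residues(seq[lo:hi])


def _hamming_count(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))
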