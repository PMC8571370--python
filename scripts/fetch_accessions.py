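#!/usr/bin/env python
"""Download the deposited INSDC sequences used by the optional reproduction
checks in tests/test_acceptance.py. Requires network access; the analysis
pipeline itself never touches the network.

Usage:
    python scripts/fetch_accessions.py [--out data/accessions] [--email you@x]

Writes:
    coi_direct.fasta    LC571524-LC571526  (COI direct-sequencing haplotypes)
    s12_direct.fasta    LC605705-LC605707  (12S direct-sequencing haplotypes)
    dloop_direct.fasta  LC605749           (Dloop direct-sequencing haplotype)
    references.fasta    NC_004251, NC_028024 (reference mitogenomes)
"""

from __future__ import annotations

import argparse
from pathlib import Path

from Bio import Entrez, SeqIO

SETS = {
    "coi_direct.fasta": ["LC571524", "LC571525", "LC571526"],
    "s12_direct.fasta": ["LC605705", "LC605706", "LC605707"],
    "dloop_direct.fasta": ["LC605749"],
    "references.fasta": ["NC_004251", "NC_028024"],
}


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=Path("data/accessions"))
    ap.add_argument("--email", default="anonymous@example.org")
    args = ap.parse_args()
    Entrez.email = args.email
    args.out.mkdir(parents=True, exist_ok=True)
    for fname, accs in SETS.items():
        with Entrez.efetch(db="nucleotide", id=",".join(accs),
                           rettype="fasta", retmode="text") as handle:
            records = list(SeqIO.parse(handle, "fasta"))
        if len(records) != len(accs):
            raise RuntimeError(f"expected {len(accs)} records for {fname}, "
                               f"got {len(records)}")
        SeqIO.write(records, args.out / fname, "fasta")
        print(f"wrote {args.out / fname} ({len(records)} records)")


if __name__ == "__main__":
    main()
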