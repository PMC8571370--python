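"""Synthetic clone-library generator with ground truth.

The generator emulates the data-generating process of a cloning experiment on
PCR-amplified mtDNA: one genuine haplotype per individual present in many
identical clones, a few rare heteroplasmic templates a handful of
substitutions away, several nuclear pseudogene (NUMT) loci at substantial
divergence carrying indels and (for coding regions) nonsense codons, and
per-clone polymerase errors accumulated over the amplification cycles.

Two amplification models are provided. The genealogy model follows molecule
counts through the cycles: an initial pool is drawn from the template weights,
every molecule is copied with the per-cycle efficiency, and each copy acquires
one synthesis round of errors; sampled clones then draw their error rounds
according to their synthesis depth. (Counts, not individual molecules, are
tracked — at 35 cycles the pool reaches ~1e12 — so sampled lineages are
treated as independent given their depth; see the methods note.) The fast
binomial model instead draws each clone's synthesis depth directly as
Binomial(cycles, 1/2), the depth law of a random final molecule under ideal
doubling.

NUMT divergence is realized with the Kimura-model forward probabilities, so
the K2P distance of a simulated NUMT to the genuine haplotype is an unbiased
estimate of its drawn target divergence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np

from .seqio import SequenceRecord, write_fasta

_BASES = "ACGT"
_TS = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TV = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for one simulated region library."""

    region_kind: Literal["coding", "noncoding"] = "coding"
    fragment_length: Optional[int] = None  # default 807 coding / 820 noncoding
    base_composition: tuple[float, float, float, float] = (0.31, 0.18, 0.17, 0.34)
    n_heteroplasmic: int = 2
    het_subs_range: tuple[int, int] = (3, 10)
    het_fraction: float = 0.05  # per heteroplasmic template
    n_numt_loci: int = 3
    numt_divergence_range: Optional[tuple[float, float]] = None  # subs/site
    numt_indel_rate: Optional[float] = None  # per site
    indel_mean_length: float = 2.0  # geometric law
    numt_weight: float = 0.02  # per locus
    kappa: float = 4.0  # transition:transversion odds
    taq_error_rate: float = 1.0e-4  # per base per synthesis
    cycles: int = 35
    amplification_model: Literal["genealogy", "binomial"] = "genealogy"
    efficiency: float = 0.8  # per cycle, genealogy model
    initial_pool: int = 1000
    n_clones: int = 30
    seed: int = 0

    @property
    def length(self) -> int:
        if self.fragment_length is not None:
            return self.fragment_length
        return 807 if self.region_kind == "coding" else 820

    @property
    def divergence_range(self) -> tuple[float, float]:
        if self.numt_divergence_range is not None:
            return self.numt_divergence_range
        return (0.07, 0.24) if self.region_kind == "coding" else (0.07, 0.70)

    @property
    def indel_rate(self) -> float:
        if self.numt_indel_rate is not None:
            return self.numt_indel_rate
        return 0.001 if self.region_kind == "coding" else 0.005

    @property
    def genuine_weight(self) -> float:
        return 1.0 - self.n_heteroplasmic * self.het_fraction \
            - self.n_numt_loci * self.numt_weight

    def validate(self) -> None:
        for rate in (self.het_fraction, self.numt_weight, self.taq_error_rate,
                     self.efficiency):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.genuine_weight <= 0:
            raise ValueError("template weights exceed 1; nothing left for genuine")
        lo, hi = self.het_subs_range
        if lo > hi or lo < 0:
            raise ValueError("het_subs_range must be ordered and nonnegative")
        lo, hi = self.divergence_range
        if lo > hi or lo < 0:
            raise ValueError("numt divergence range must be ordered")
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise ValueError("base composition must sum to 1")


@dataclass(frozen=True)
class MutationOp:
    """One ledgered mutation, applied in order to the genuine sequence."""

    kind: Literal["sub", "ins", "del"]
    pos: int  # position at application time
    from_seq: str = ""
    to_seq: str = ""


@dataclass
class Template:
    record: SequenceRecord
    label: str  # genuine | heteroplasmic | numt
    weight: float
    ledger: list[MutationOp] = field(default_factory=list)
    target_divergence: Optional[float] = None
    flagged: bool = False  # coding NUMT redraw limit hit


@dataclass
class SimTruth:
    templates: list[Template]
    frame: int  # genuine reading frame (coding), 0 otherwise
    config: SimConfig

    @property
    def genuine(self) -> Template:
        return next(t for t in self.templates if t.label == "genuine")


@dataclass(frozen=True)
class CloneProvenance:
    clone_id: str
    template_id: str
    template_label: str
    depth: int  # synthesis rounds
    n_errors: int
    error_ledger: tuple[MutationOp, ...] = ()


def apply_ledger(genuine: str, ledger: Sequence[MutationOp]) -> str:
    """Replay a mutation ledger; reproduces the template exactly."""
    s = list(genuine)
    for op in ledger:
        if op.kind == "sub":
            if s[op.pos] != op.from_seq:
                raise ValueError(f"ledger replay mismatch at {op.pos}")
            s[op.pos] = op.to_seq
        elif op.kind == "del":
            if "".join(s[op.pos : op.pos + len(op.from_seq)]) != op.from_seq:
                raise ValueError(f"ledger replay mismatch at {op.pos}")
            del s[op.pos : op.pos + len(op.from_seq)]
        elif op.kind == "ins":
            s[op.pos:op.pos] = list(op.to_seq)
        else:
            raise ValueError(op.kind)
    return "".join(s)


def kimura_forward(d: float, kappa: float) -> tuple[float, float]:
    """Expected observed transition (P) and transversion (Q) proportions for a
    Kimura-model divergence ``d`` with transition:transversion odds kappa:1.

    Inverse of the K2P distance formula: plugging (P, Q) back in returns d.
    """
    v = d / (4.0 * kappa + 4.0)
    u = kappa * d / (2.0 * (kappa + 1.0))
    Q = 0.5 * (1.0 - math.exp(-8.0 * v))
    P = 0.25 - 0.5 * math.exp(-4.0 * (u + v)) + 0.25 * math.exp(-8.0 * v)
    return P, Q


def _substitute(rng: np.random.Generator, base: str, kappa: float) -> str:
    if rng.random() < kappa / (kappa + 1.0):
        return _TS[base]
    return _TV[base][rng.integers(2)]


def _draw_genuine(rng: np.random.Generator, cfg: SimConfig) -> str:
    p = np.asarray(cfg.base_composition)
    L = cfg.length
    seq = list(rng.choice(list(_BASES), size=L, p=p))
    if cfg.region_kind == "coding":
        from .mitocodon import STOP_CODONS

        for i in range(0, L - 2, 3):
            while "".join(seq[i : i + 3]) in STOP_CODONS:
                seq[i : i + 3] = rng.choice(list(_BASES), size=3, p=p)
    return "".join(seq)


def _mutate_heteroplasmic(rng, genuine: str, cfg: SimConfig) -> list[MutationOp]:
    u = int(rng.integers(cfg.het_subs_range[0], cfg.het_subs_range[1] + 1))
    positions = rng.choice(len(genuine), size=u, replace=False)
    return [
        MutationOp("sub", int(p), genuine[p], _substitute(rng, genuine[p], cfg.kappa))
        for p in sorted(map(int, positions))
    ]


def _mutate_numt(rng, genuine: str, cfg: SimConfig, d: float) -> list[MutationOp]:
    P, Q = kimura_forward(d, cfg.kappa)
    ops: list[MutationOp] = []
    for pos, base in enumerate(genuine):
        r = rng.random()
        if r < P:
            ops.append(MutationOp("sub", pos, base, _TS[base]))
        elif r < P + Q:
            ops.append(MutationOp("sub", pos, base, _TV[base][rng.integers(2)]))
    # indels applied after substitutions; positions valid at application time
    seq_len = len(genuine)
    mutated = apply_ledger(genuine, ops)
    n_indels = rng.poisson(cfg.indel_rate * seq_len)
    geom_p = 1.0 / cfg.indel_mean_length
    current = mutated
    for _ in range(n_indels):
        length = int(rng.geometric(geom_p))
        if rng.random() < 0.5 and len(current) > length:
            pos = int(rng.integers(0, len(current) - length))
            op = MutationOp("del", pos, from_seq=current[pos : pos + length])
        else:
            pos = int(rng.integers(0, len(current) + 1))
            ins = "".join(rng.choice(list(_BASES), size=length,
                                     p=np.asarray(cfg.base_composition)))
            op = MutationOp("ins", pos, to_seq=ins)
        ops.append(op)
        current = apply_ledger(current, [op])
    return ops


def _numt_is_pseudogene_like(seq: str, ledger: Sequence[MutationOp]) -> bool:
    """Coding-region check: at least one frameshift indel or internal stop."""
    from .mitocodon import translate_mito

    has_fs = any(
        op.kind in ("ins", "del")
        and len(op.to_seq or op.from_seq) % 3 != 0
        for op in ledger
    )
    if has_fs:
        return True
    return "*" in translate_mito(seq, 0)[:-1] if len(seq) >= 3 else False


def generate_truth(cfg: SimConfig) -> SimTruth:
    """Draw the template pool (genuine, heteroplasmic, NUMT) with ledgers."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genuine_seq = _draw_genuine(rng, cfg)
    region = "COI" if cfg.region_kind == "coding" else "other"
    templates = [
        Template(
            record=SequenceRecord("SIM-genuine", genuine_seq, region=region,
                                  individual="SIM", role="simulated"),
            label="genuine",
            weight=cfg.genuine_weight,
        )
    ]
    for h in range(cfg.n_heteroplasmic):
        ledger = _mutate_heteroplasmic(rng, genuine_seq, cfg)
        seq = apply_ledger(genuine_seq, ledger)
        templates.append(
            Template(
                record=SequenceRecord(f"SIM-het{h + 1}", seq, region=region,
                                      individual="SIM", role="simulated"),
                label="heteroplasmic",
                weight=cfg.het_fraction,
                ledger=ledger,
            )
        )
    lo, hi = cfg.divergence_range
    for m in range(cfg.n_numt_loci):
        d = float(rng.uniform(lo, hi))
        flagged = False
        for attempt in range(100):
            ledger = _mutate_numt(rng, genuine_seq, cfg, d)
            seq = apply_ledger(genuine_seq, ledger)
            if cfg.region_kind != "coding" or d < 0.10 \
                    or _numt_is_pseudogene_like(seq, ledger):
                break
        else:
            flagged = True
        templates.append(
            Template(
                record=SequenceRecord(f"SIM-numt{m + 1}", seq, region=region,
                                      individual="SIM", role="simulated"),
                label="numt",
                weight=cfg.numt_weight,
                ledger=ledger,
                target_divergence=d,
                flagged=flagged,
            )
        )
    return SimTruth(templates=templates, frame=0, config=cfg)


def _apply_error_rounds(rng, seq: str, depth: int, mu: float, kappa: float
                        ) -> tuple[str, list[MutationOp]]:
    s = list(seq)
    ops: list[MutationOp] = []
    for _ in range(depth):
        n_err = rng.binomial(len(s), mu)
        if n_err == 0:
            continue
        positions = rng.choice(len(s), size=n_err, replace=False)
        for p in sorted(map(int, positions)):
            new = _substitute(rng, s[p], kappa) if s[p] in _BASES else "N"
            ops.append(MutationOp("sub", p, s[p], new))
            s[p] = new
    return "".join(s), ops


def simulate_pcr_library(truth: SimTruth, cfg: Optional[SimConfig] = None
                         ) -> tuple[list[SequenceRecord], list[CloneProvenance]]:
    """Amplify the template pool and sample clones with provenance labels."""
    cfg = cfg or truth.config
    rng = np.random.default_rng(cfg.seed + 1)
    weights = np.array([t.weight for t in truth.templates])
    weights = weights / weights.sum()
    n_templates = len(truth.templates)

    if cfg.amplification_model == "genealogy":
        counts = np.zeros((n_templates, cfg.cycles + 1), dtype=np.int64)
        counts[:, 0] = rng.multinomial(cfg.initial_pool, weights)
        for _ in range(cfg.cycles):
            copies = rng.binomial(counts[:, :-1], cfg.efficiency)
            counts[:, 1:] += copies
        total = counts.sum()
        if total < cfg.n_clones:
            raise ValueError("pool extinction: fewer molecules than clones requested")
        flat = counts.reshape(-1).astype(float)
        picks = []
        for _ in range(cfg.n_clones):  # without replacement
            p = flat / flat.sum()
            k = int(rng.choice(flat.size, p=p))
            flat[k] -= 1
            picks.append(divmod(k, cfg.cycles + 1))
    else:
        picks = [
            (int(rng.choice(n_templates, p=weights)),
             int(rng.binomial(cfg.cycles, 0.5)))
            for _ in range(cfg.n_clones)
        ]

    clones, provenance = [], []
    for idx, (t_idx, depth) in enumerate(picks):
        template = truth.templates[t_idx]
        seq, ops = _apply_error_rounds(rng, template.record.residues, depth,
                                       cfg.taq_error_rate, cfg.kappa)
        cid = f"SIM-C{idx + 1}"
        clones.append(
            SequenceRecord(cid, seq, region=template.record.region,
                           individual="SIM", role="clone")
        )
        provenance.append(
            CloneProvenance(
                clone_id=cid,
                template_id=template.record.id,
                template_label=template.label,
                depth=int(depth),
                n_errors=len(ops),
                error_ledger=tuple(ops),
            )
        )
    return clones, provenance


def emit_fixture(truth: SimTruth, clones: Sequence[SequenceRecord],
                 provenance: Sequence[CloneProvenance], out_dir) -> dict[str, Path]:
    """Write direct.fasta, clones.fasta, templates.fasta and truth.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    direct = replace(truth.genuine.record, id="SIM-direct", role="direct")
    paths = {
        "direct": out / "direct.fasta",
        "clones": out / "clones.fasta",
        "templates": out / "templates.fasta",
        "truth": out / "truth.tsv",
    }
    write_fasta([direct], paths["direct"])
    write_fasta(list(clones), paths["clones"])
    write_fasta([t.record for t in truth.templates], paths["templates"])
    with open(paths["truth"], "w") as fh:
        fh.write("clone_id\ttemplate_id\ttemplate_label\tdepth\tn_taq_errors\n")
        for p in provenance:
            fh.write(f"{p.clone_id}\t{p.template_id}\t{p.template_label}\t"
                     f"{p.depth}\t{p.n_errors}\n")
    return paths
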