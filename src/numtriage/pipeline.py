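"""End-to-end per-region analysis: ingest -> align -> distances -> tree ->
codon diagnostics -> triage -> chromatogram prediction -> reports.

Clone ids are expected to start with the individual's label followed by a
hyphen (``PJK1-C25`` belongs to ``PJK1``); a direct-sequencing read for an
individual shares that prefix. Clones whose insert length deviates more than
20% from the region's expected size are excluded up front and listed, the way
wrong-size inserts are discarded before sequencing.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from . import __version__
from .chromatogram import multipeak_counts, predict_site_signals
from .evodist import DistanceMatrix, distance_matrix
from .mitocodon import annotate_substitutions, infer_frame
from .msa import Alignment, AlignParams, progressive_align, trim_to_window
from .phylo import bootstrap_support, neighbor_joining, to_newick
from .seqio import (DEFAULT_PRIMERS, EXPECTED_PRODUCT_SIZE, SequenceRecord,
                    read_fasta, trim_primers, write_fasta)
from .triage import (GenuineCall, GenuineUndeterminedError, NoGenuineMatchError,
                     TriageConfig, TriageReport, assign_groups, classify_clones,
                     divergence_summary, identify_genuine)

logger = logging.getLogger(__name__)


def individual_from_id(rec_id: str) -> str:
    return rec_id.split("-", 1)[0]


@dataclass
class RegionInputs:
    clones: Path
    direct: Optional[Path] = None
    references: Optional[Path] = None
    outgroup: Optional[str] = None  # id of the outgroup reference


@dataclass
class RunConfig:
    regions: dict[str, RegionInputs]
    out_dir: Path = Path("numtriage_out")
    triage: TriageConfig = field(default_factory=TriageConfig)
    align: AlignParams = field(default_factory=AlignParams)
    bootstrap_B: int = 1000
    seed: int = 0
    trim_primer_footprints: bool = False
    insert_size_tolerance: float = 0.20
    expected_insert: Optional[int] = None  # default: region product size
    report_formats: tuple[str, ...] = ("tsv", "json")
    peak_threshold: float = 0.10

    def validate(self) -> None:
        if not self.regions:
            raise ValueError("region list is empty")
        for name, inp in self.regions.items():
            if not Path(inp.clones).exists():
                raise FileNotFoundError(f"{name}: clones file {inp.clones} missing")
            for p in (inp.direct, inp.references):
                if p is not None and not Path(p).exists():
                    raise FileNotFoundError(f"{name}: input {p} missing")


@dataclass
class RegionResult:
    region: str
    report: TriageReport
    alignment: Alignment
    tree_newick: Optional[str]
    excluded_clones: list[str]
    peak_summary: dict[str, tuple[int, int, int]]
    log_lines: list[str]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


def _filter_inserts(clones: Sequence[SequenceRecord], expected: int,
                    tol: float, log: list[str]) -> tuple[list, list[str]]:
    keep, dropped = [], []
    for c in clones:
        L = len(c.degapped())
        if abs(L - expected) > tol * expected:
            dropped.append(c.id)
        else:
            keep.append(c)
    if dropped:
        log.append(f"excluded {len(dropped)} clones with insert length deviating "
                   f">{tol:.0%} from {expected}: {', '.join(dropped)}")
    return keep, dropped


def run_region(cfg: RunConfig, region: str) -> RegionResult:
    """Run the full analysis for one region; artifacts under out_dir/region."""
    inp = cfg.regions[region]
    log: list[str] = [f"numtriage {__version__} region={region} seed={cfg.seed}"]
    rng_seed = cfg.seed

    def stage(name):
        log.append(f"stage: {name}")
        return name

    try:
        stage("read")
        clones = read_fasta(inp.clones, region=region if region in
                            ("COI", "12S", "Dloop") else "other", role="clone")
        direct = (read_fasta(inp.direct, region=clones[0].region, role="direct")
                  if inp.direct else [])
        refs = (read_fasta(inp.references, region=clones[0].region,
                           role="reference") if inp.references else [])
        for rec in clones + direct:
            rec.individual = individual_from_id(rec.id)
    except Exception as e:  # noqa: BLE001
        raise StageError("read", e) from e

    try:
        stage("trim_primers")
        if cfg.trim_primer_footprints and region in DEFAULT_PRIMERS:
            primers = DEFAULT_PRIMERS[region]
            clones = [trim_primers(c, primers) for c in clones]
            direct = [trim_primers(d, primers) for d in direct]
        expected = cfg.expected_insert or int(
            np.median([len(c.degapped()) for c in clones])
        )
        clones, dropped = _filter_inserts(clones, expected,
                                          cfg.insert_size_tolerance, log)
        if not clones:
            raise ValueError("all clones excluded by the insert-size filter")
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("trim_primers", e) from e

    try:
        stage("align")
        aln = progressive_align(clones + direct + refs, cfg.align)
        if direct:
            aln = trim_to_window(aln, [d.id for d in direct])
            log.append(f"trimmed to window of shortest direct read; "
                       f"length {aln.length}")
    except Exception as e:  # noqa: BLE001
        raise StageError("align", e) from e

    try:
        stage("distances")
        dm = distance_matrix(aln)
        if dm.undefined_pairs:
            log.append(f"{len(dm.undefined_pairs)} undefined (saturated) pairs")
    except Exception as e:  # noqa: BLE001
        raise StageError("distances", e) from e

    tree = None
    tree_newick = None
    try:
        stage("tree")
        if len(aln.records) >= 4 and not dm.undefined_pairs:
            tree = bootstrap_support(aln, B=cfg.bootstrap_B, seed=rng_seed)
            tree_newick = to_newick(tree, support_threshold=60.0)
        elif dm.undefined_pairs:
            log.append("tree skipped: undefined distances; "
                       "distance-based grouping used")
    except Exception as e:  # noqa: BLE001
        raise StageError("tree", e) from e

    try:
        stage("identify_genuine")
        genuine_by_ind: dict[str, Optional[GenuineCall]] = {}
        aligned = {r.id: r for r in aln.records}
        clone_rows = [aligned[c.id] for c in clones]
        for ind in sorted({c.individual for c in clones}):
            ind_clones = [c for c in clone_rows if c.individual == ind]
            ind_direct = next(
                (aligned[d.id] for d in direct if d.individual == ind), None
            )
            try:
                call = identify_genuine(ind_clones, ind_direct, cfg.triage)
                log.append(f"{ind}: genuine {call.haplotype.id} supported by "
                           f"{len(call.supporting_clones)} clones "
                           f"(direct={call.from_direct})")
            except (GenuineUndeterminedError, NoGenuineMatchError) as e:
                call = None
                log.append(f"{ind}: {e}")
            genuine_by_ind[ind] = call
    except Exception as e:  # noqa: BLE001
        raise StageError("identify_genuine", e) from e

    try:
        stage("codon")
        annotations = {}
        genuine_calls = {i: c for i, c in genuine_by_ind.items() if c}
        if clones[0].region == "COI" and genuine_calls:
            frames = {}
            for ind, call in genuine_calls.items():
                fc = infer_frame(call.haplotype.residues)
                frames[ind] = fc.frame
                log.append(f"{ind}: frame {fc.frame}, stops/frame {fc.stop_counts}")
            for c in clone_rows:
                call = genuine_calls.get(c.individual)
                if call is None:
                    continue
                annotations[c.id] = annotate_substitutions(
                    call.haplotype.residues, c.residues,
                    frames[c.individual])
    except Exception as e:  # noqa: BLE001
        raise StageError("codon", e) from e

    try:
        stage("triage")
        # anchor the genuine clade on every genuine-identical clone
        genuine_ids = sorted(
            {c.haplotype.id for c in genuine_calls.values()}
            | {cid for c in genuine_calls.values() for cid in c.supporting_clones}
        )
        if not genuine_ids:
            raise GenuineUndeterminedError("no individual has a genuine haplotype")
        scope = [c.id for c in clone_rows] + [d.id for d in direct]
        groups = assign_groups(dm.submatrix(scope), genuine_ids, tree,
                               cfg.triage, region=clones[0].region,
                               outgroup=inp.outgroup)
        report = classify_clones(clone_rows, genuine_by_ind, groups, dm,
                                 annotations, cfg.triage,
                                 region=clones[0].region)
        if len(groups.groups()) >= 2:
            report.divergence = divergence_summary(
                groups, aln, dm, B=max(100, cfg.bootstrap_B // 5), seed=rng_seed
            )
        for th, val in (("taq_max_diffs", cfg.triage.taq_max_diffs),
                        ("heteroplasmy_min_diffs", cfg.triage.heteroplasmy_min_diffs),
                        ("group_link_cutoff",
                         cfg.triage.group_link_cutoff.get(clones[0].region)),
                        ("clade_support_min", cfg.triage.clade_support_min)):
            log.append(f"threshold {th}={val}")
    except Exception as e:  # noqa: BLE001
        raise StageError("triage", e) from e

    try:
        stage("chromatogram")
        peak_summary = {}
        for ind in sorted({c.individual for c in clones}):
            rows = [aligned[c.id] for c in clones if c.individual == ind]
            sub = Alignment(list(rows), provenance=f"{region}:{ind} clones")
            w = [1.0 / len(rows)] * len(rows)
            profile = predict_site_signals(sub, w, threshold=cfg.peak_threshold)
            peak_summary[ind] = multipeak_counts(profile)
            log.append(f"{ind}: predicted peaks double/triple/gap-disrupted "
                       f"{peak_summary[ind]}")
    except Exception as e:  # noqa: BLE001
        raise StageError("chromatogram", e) from e

    return RegionResult(region=region, report=report, alignment=aln,
                        tree_newick=tree_newick, excluded_clones=dropped,
                        peak_summary=peak_summary, log_lines=log)


def write_reports(result: RegionResult, out_dir,
                  formats: Sequence[str] = ("tsv", "json")) -> dict[str, Path]:
    out = Path(out_dir) / result.region
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    if "tsv" in formats:
        paths["report_tsv"] = out / "triage_report.tsv"
        result.report.to_tsv(paths["report_tsv"])
        if result.report.divergence is not None:
            paths["divergence_tsv"] = out / "divergence_summary.tsv"
            result.report.divergence.to_csv(paths["divergence_tsv"], sep="\t",
                                            index=False)
    if "json" in formats:
        paths["report_json"] = out / "triage_report.json"
        with open(paths["report_json"], "w") as fh:
            json.dump(result.report.to_json_dict(), fh, indent=1, default=str)
    paths["alignment"] = out / "alignment.fasta"
    write_fasta(result.alignment.records, paths["alignment"])
    if result.tree_newick:
        paths["tree"] = out / "tree.nwk"
        Path(paths["tree"]).write_text(result.tree_newick + "\n")
    paths["log"] = out / "run.log"
    Path(paths["log"]).write_text("\n".join(result.log_lines) + "\n")
    return paths


def run(cfg: RunConfig) -> dict[str, RegionResult]:
    """Run all configured regions; a failing region does not stop the rest."""
    cfg.validate()
    results: dict[str, RegionResult] = {}
    for region in cfg.regions:
        try:
            res = run_region(cfg, region)
            write_reports(res, cfg.out_dir, cfg.report_formats)
            results[region] = res
        except StageError as e:
            logger.error("region %s aborted: %s", region, e)
    return results
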