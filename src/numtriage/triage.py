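"""Clone triage: genuine haplotypes, Taq error variants, heteroplasmy, NUMTs.

The decision procedure mirrors how clone libraries of PCR-amplified mtDNA are
adjudicated. The genuine haplotype of an individual is the clone haplotype
identical to its direct-sequencing read (or, failing a direct read, the
dominant identical clone set). Haplotypes are then grouped — primarily by the
supported clade containing the genuine haplotypes on the NJ tree, with
single-linkage clustering on K2P distance as the fallback — and every clone is
labeled:

* ``genuine``            — identical to the individual's genuine haplotype;
* ``pcr_error_variant``  — in the genuine group, 1..t differences (default
  t=2), the burden expected from polymerase error over the amplification;
* ``heteroplasmy``       — in the genuine group but >= 3 differences, too many
  for polymerase error alone;
* ``numt``               — outside the genuine group (substantial divergence,
  typically with stops/frameshifts in coding regions);
* ``ambiguous``          — no genuine haplotype could be determined, or the
  grouping evidence conflicts.

Stop codons alone never decide a label: one genuine-group heteroplasmic
haplotype may carry a stop, so codon evidence is recorded as corroboration.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .evodist import DistanceMatrix, difference_count, mean_distance_with_se
from .mitocodon import CodonAnnotation
from .msa import Alignment
from .phylo import Tree, midpoint_root, root_at_outgroup
from .seqio import SequenceRecord

logger = logging.getLogger(__name__)

LABELS = ("genuine", "pcr_error_variant", "heteroplasmy", "numt", "ambiguous")

_FAR = 1e6  # sentinel distance for undefined pairs in single-linkage


@dataclass(frozen=True)
class TriageConfig:
    taq_max_diffs: int = 2  # t: <= t differences -> Taq error variant
    heteroplasmy_min_diffs: int = 3
    genuine_radius: Mapping[str, float] = field(
        default_factory=lambda: {"COI": 2.5, "12S": 2.5, "Dloop": 5.0, "other": 2.5}
    )  # K2P %, sanity flag for genuine-group members
    group_link_cutoff: Mapping[str, float] = field(
        default_factory=lambda: {"COI": 5.0, "12S": 1.0, "Dloop": 10.0, "other": 5.0}
    )  # K2P % for single-linkage grouping
    min_genuine_support: int = 2  # clone multiplicity when no direct read
    use_tree_clades: bool = True
    clade_support_min: float = 60.0
    diff_mode: str = "events"  # a contiguous indel counts once

    def __post_init__(self) -> None:
        if not 0 <= self.taq_max_diffs < self.heteroplasmy_min_diffs:
            raise ValueError("need 0 <= taq_max_diffs < heteroplasmy_min_diffs")
        if any(r <= 0 for r in self.genuine_radius.values()):
            raise ValueError("genuine radii must be positive")


class GenuineUndeterminedError(ValueError):
    pass


class NoGenuineMatchError(ValueError):
    pass


@dataclass(frozen=True)
class GenuineCall:
    haplotype: SequenceRecord  # the genuine haplotype (aligned row)
    supporting_clones: tuple[str, ...]
    from_direct: bool


def identify_genuine(clones: Sequence[SequenceRecord],
                     direct: Optional[SequenceRecord],
                     cfg: TriageConfig = TriageConfig()) -> GenuineCall:
    """Determine the genuine haplotype of one individual and region.

    All records must be rows of the same trimmed alignment. With a direct
    read, the genuine haplotype is the clone haplotype with zero differences
    (events mode) to it; without one, the haplotype shared identically by the
    most clones, requiring multiplicity >= ``min_genuine_support``.
    """
    if not clones:
        raise ValueError("no clones supplied")
    if direct is not None:
        matches = tuple(
            c.id for c in clones
            if difference_count(c.residues, direct.residues, "events") == 0
        )
        if not matches:
            raise NoGenuineMatchError(
                f"no clone identical to direct read {direct.id}"
            )
        rep = next(c for c in clones if c.id == matches[0])
        return GenuineCall(haplotype=rep, supporting_clones=matches,
                           from_direct=True)
    classes: dict[str, list[SequenceRecord]] = {}
    for c in clones:
        classes.setdefault(c.residues, []).append(c)
    best = max(
        classes.values(),
        key=lambda grp: (len(grp), min(c.id for c in grp)),
    )
    if len(best) < cfg.min_genuine_support:
        raise GenuineUndeterminedError(
            f"no haplotype reaches multiplicity {cfg.min_genuine_support}"
        )
    rep = min(best, key=lambda c: c.id)
    return GenuineCall(haplotype=rep,
                       supporting_clones=tuple(sorted(c.id for c in best)),
                       from_direct=False)


@dataclass
class GroupAssignment:
    group_of: dict[str, str]  # haplotype id -> group letter
    genuine_group: str  # always "A"
    method: str  # "tree" or "single-linkage"
    conflicted: tuple[str, ...] = ()  # ids whose tree/distance groups disagree
    notes: list[str] = field(default_factory=list)

    def members(self, group: str) -> list[str]:
        return sorted(i for i, g in self.group_of.items() if g == group)

    def groups(self) -> list[str]:
        return sorted(set(self.group_of.values()))


def _single_linkage(dm: DistanceMatrix, cutoff_frac: float) -> dict[str, int]:
    vals = dm.values.copy()
    vals[np.isnan(vals)] = _FAR
    n = len(dm.labels)
    if n == 1:
        return {dm.labels[0]: 1}
    Z = linkage(squareform(vals, checks=False), method="single")
    flat = fcluster(Z, t=cutoff_frac, criterion="distance")
    return dict(zip(dm.labels, map(int, flat)))


def assign_groups(distances: DistanceMatrix,
                  genuine_ids: Sequence[str],
                  tree: Optional[Tree] = None,
                  cfg: TriageConfig = TriageConfig(),
                  region: str = "other",
                  outgroup: Optional[str] = None) -> GroupAssignment:
    """Partition haplotypes into groups and name the genuine group 'A'.

    Primary (tree available and ``use_tree_clades``): the tree evidence for
    the genuine group is the leaf set of the smallest clade containing all
    genuine anchor ids whose support reaches ``clade_support_min`` (the root
    always qualifies); the distance evidence is the single-linkage group of
    the genuine ids at the region's K2P cutoff. Group A is the union of the
    two, and members supported by only one line of evidence are recorded as
    conflicted. Fallback (no tree): single-linkage alone. Groups beyond A are
    lettered by increasing mean defined K2P distance from A.
    """
    labels = list(distances.labels)
    genuine_ids = [g for g in genuine_ids if g in set(labels)]
    if not genuine_ids:
        raise ValueError("no genuine ids among the distance labels")
    cutoff = cfg.group_link_cutoff.get(region, 5.0) / 100.0
    sl = _single_linkage(distances, cutoff)
    notes: list[str] = []

    gen_groups = {sl[g] for g in genuine_ids}
    if len(gen_groups) > 1:
        notes.append(
            "genuine haplotypes split across single-linkage groups; "
            "grouping flagged ambiguous"
        )
        warnings.warn(notes[-1])
    dist_a = {l for l in labels if sl[l] in gen_groups}

    method = "single-linkage"
    conflicted: tuple[str, ...] = ()
    if tree is not None and cfg.use_tree_clades:
        rooted = root_at_outgroup(tree, outgroup) if outgroup else midpoint_root(tree)
        gen = frozenset(genuine_ids)
        # MRCA of the anchors, then walk up through poorly supported edges —
        # but never absorb haplotypes beyond the single-linkage cutoff from
        # the anchors (low support must not drag divergent groups into A)
        node = None
        for cand in rooted.root.walk():
            ls = cand.leaf_names()
            if gen <= ls and (node is None or len(ls) < len(node.leaf_names())):
                node = cand
        anchor_idx = [labels.index(g) for g in genuine_ids]

        def _near_anchors(name: str) -> bool:
            if name not in set(labels):
                return False  # references etc. never join A
            row = distances.values[labels.index(name), anchor_idx]
            defined = row[~np.isnan(row)]
            return bool(defined.size) and float(defined.min()) <= cutoff

        while (node.parent is not None and node.support is not None
               and node.support < cfg.clade_support_min):
            added = node.parent.leaf_names() - node.leaf_names()
            if not all(_near_anchors(n) for n in added):
                break
            node = node.parent
        # prune: clade members beyond single-linkage reach of the anchors are
        # long NUMT branches that NJ nested inside the near-zero genuine
        # radiation, not genuine-group evidence
        tree_a = {l for l in node.leaf_names() if _near_anchors(l)}
        a_members = tree_a | dist_a
        conflicted = tuple(sorted(tree_a ^ dist_a))
        if conflicted:
            notes.append(
                "tree-based and distance-based genuine-group membership "
                f"disagree for: {', '.join(conflicted)}"
            )
        method = "tree"
    else:
        a_members = dist_a

    rest = [l for l in labels if l not in a_members]
    group_of = {l: "A" for l in a_members}
    if rest:
        sub = distances.submatrix(rest)
        sub_sl = _single_linkage(sub, cutoff)
        # order remaining groups by mean defined distance to A
        a_idx = [labels.index(l) for l in a_members]
        means = {}
        for gid in sorted(set(sub_sl.values())):
            mem = [l for l in rest if sub_sl[l] == gid]
            cells = distances.values[np.ix_([labels.index(l) for l in mem], a_idx)]
            defined = cells[~np.isnan(cells)]
            means[gid] = float(defined.mean()) if defined.size else math.inf
            if not defined.size:
                notes.append(
                    f"group of {mem} has no defined distance to A (saturation); "
                    "ordered last and flagged"
                )
        order = sorted(means, key=lambda g: (means[g], g))
        letters = [chr(ord("B") + k) for k in range(len(order))]
        for gid, letter in zip(order, letters):
            for l in rest:
                if sub_sl[l] == gid:
                    group_of[l] = letter

    return GroupAssignment(group_of=group_of, genuine_group="A", method=method,
                           conflicted=conflicted, notes=notes)


@dataclass
class TriageReport:
    per_clone: pd.DataFrame  # one row per input clone
    groups: GroupAssignment
    genuine_by_individual: dict[str, Optional[GenuineCall]]
    divergence: Optional[pd.DataFrame] = None

    def label_counts(self) -> dict[str, int]:
        return self.per_clone["label"].value_counts().to_dict()

    def to_tsv(self, path) -> None:
        self.per_clone.to_csv(path, sep="\t", index=False)

    def to_json_dict(self) -> dict:
        return {
            "clones": self.per_clone.to_dict(orient="records"),
            "groups": {g: self.groups.members(g) for g in self.groups.groups()},
            "group_method": self.groups.method,
            "divergence": (
                self.divergence.to_dict(orient="records")
                if self.divergence is not None else None
            ),
        }


def classify_clones(clones: Sequence[SequenceRecord],
                    genuine_by_individual: Mapping[str, Optional[GenuineCall]],
                    groups: GroupAssignment,
                    distances: DistanceMatrix,
                    codon_annotations: Optional[Mapping[str, CodonAnnotation]] = None,
                    cfg: TriageConfig = TriageConfig(),
                    region: str = "other") -> TriageReport:
    """Label every clone with supporting evidence.

    ``clones`` are rows of the trimmed alignment; ``genuine_by_individual``
    maps an individual to its genuine call (None when undetermined, which
    makes that individual's clones ambiguous).
    """
    t = cfg.taq_max_diffs
    hmin = cfg.heteroplasmy_min_diffs
    radius = cfg.genuine_radius.get(region, 2.5)
    ann = codon_annotations or {}
    rows = []
    for clone in clones:
        call = genuine_by_individual.get(clone.individual)
        rec: dict = {
            "clone_id": clone.id,
            "individual": clone.individual,
            "group": groups.group_of.get(clone.id),
            "label": "ambiguous",
            "diffs_events": None,
            "diffs_columns": None,
            "k2p_to_genuine": None,
            "in_genuine_clade": groups.group_of.get(clone.id) == "A",
            "stop_count": None,
            "nonsyn_count": None,
            "notes": "",
        }
        notes = []
        a = ann.get(clone.id)
        if a is not None:
            rec["stop_count"] = a.stop_count
            rec["nonsyn_count"] = a.nonsynonymous_count
        if call is None:
            notes.append("genuine haplotype undetermined")
        else:
            g = call.haplotype
            d_ev = difference_count(clone.residues, g.residues, "events")
            d_col = difference_count(clone.residues, g.residues, "columns")
            try:
                k2p = distances.get(clone.id, g.id) * 100.0
            except ValueError:
                k2p = math.nan
            rec["diffs_events"] = d_ev
            rec["diffs_columns"] = d_col
            rec["k2p_to_genuine"] = None if math.isnan(k2p) else k2p
            d = d_ev if cfg.diff_mode == "events" else d_col
            in_a = rec["group"] == "A"
            if d == 0:
                rec["label"] = "genuine"
            elif not in_a:
                rec["label"] = "numt"
                if a is not None and (a.stop_count or a.frameshift):
                    notes.append("stop codons/frameshift corroborate numt")
            elif d <= t:
                rec["label"] = "pcr_error_variant"
            elif d >= hmin:
                rec["label"] = "heteroplasmy"
            else:
                rec["label"] = "ambiguous"
                notes.append(f"{d} differences falls between taq_max_diffs={t} "
                             f"and heteroplasmy_min_diffs={hmin}")
            if in_a and a is not None and (a.stop_count or a.frameshift):
                notes.append("pseudogene-like (stop/frameshift) in genuine group")
            if in_a and not math.isnan(k2p) and k2p > radius:
                notes.append(f"K2P {k2p:.3f}% exceeds genuine radius {radius}%")
            if clone.id in groups.conflicted:
                notes.append("group A membership supported by only one of "
                             "tree/distance evidence")
        rec["notes"] = "; ".join(notes)
        rows.append(rec)
    df = pd.DataFrame(rows)
    assert len(df) == len(clones)
    return TriageReport(per_clone=df, groups=groups,
                        genuine_by_individual=dict(genuine_by_individual))


def divergence_summary(groups: GroupAssignment, alignment: Alignment,
                       distances: DistanceMatrix, B: int = 1000,
                       seed: int = 0) -> pd.DataFrame:
    """Between-group K2P summaries: min/max/mean x100 with bootstrap SE."""
    letters = groups.groups()
    if len(letters) < 2:
        raise ValueError("need at least 2 groups")
    labels = distances.labels
    rows = []
    for ga, gb in combinations(letters, 2):
        ma, mb = groups.members(ga), groups.members(gb)
        cells = distances.values[
            np.ix_([labels.index(l) for l in ma], [labels.index(l) for l in mb])
        ]
        defined = cells[~np.isnan(cells)]
        undef_frac = 1.0 - defined.size / cells.size
        if defined.size:
            mean, se = mean_distance_with_se(alignment, ma, B=B, seed=seed,
                                             labels2=mb)
        else:
            mean, se = math.nan, math.nan
        rows.append({
            "group_1": ga,
            "group_2": gb,
            "min_pct": float(defined.min()) * 100 if defined.size else math.nan,
            "max_pct": float(defined.max()) * 100 if defined.size else math.nan,
            "mean_pct": mean * 100,
            "se_pct": se * 100,
            "undefined_fraction": undef_frac,
            "n_pairs": int(cells.size),
        })
    return pd.DataFrame(rows)
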