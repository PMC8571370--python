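import numpy as np
import pytest

from conftest import random_dna
from numtriage.evodist import distance_matrix
from numtriage.msa import Alignment
from numtriage.phylo import bootstrap_support
from numtriage.seqio import SequenceRecord
from numtriage.triage import (GenuineUndeterminedError, NoGenuineMatchError,
                              TriageConfig, assign_groups, classify_clones,
                              divergence_summary, identify_genuine)

TS = {"A": "G", "G": "A", "C": "T", "T": "C"}


def mutate(seq: str, positions) -> str:
    s = list(seq)
    for p in positions:
        s[p] = TS[s[p]]
    return "".join(s)


@pytest.fixture
def library(rng):
    """A constructed one-individual library: genuine x3, variants, NUMTs."""
    L = 400
    base = random_dna(rng, L)
    recs = [SequenceRecord(f"IND-C{i}", base, individual="IND") for i in (1, 2, 3)]
    recs.append(SequenceRecord("IND-C4", mutate(base, [10]), individual="IND"))
    recs.append(SequenceRecord("IND-C5", mutate(base, [20, 30]), individual="IND"))
    recs.append(SequenceRecord("IND-C6", mutate(base, range(40, 46)),
                               individual="IND"))  # 6 diffs: heteroplasmy-like
    numt1 = mutate(base, range(0, L, 12))  # ~8.3% substituted
    numt2 = mutate(base, range(0, L, 6))  # ~17%
    recs.append(SequenceRecord("IND-C7", numt1, individual="IND"))
    recs.append(SequenceRecord("IND-C8", numt1, individual="IND"))
    recs.append(SequenceRecord("IND-C9", numt2, individual="IND"))
    direct = SequenceRecord("IND-direct", base, individual="IND", role="direct")
    return recs, direct


class TestIdentifyGenuine:
    def test_direct_match_lists_supporting_clones(self, library):
        clones, direct = library
        call = identify_genuine(clones, direct)
        assert call.from_direct
        assert set(call.supporting_clones) == {"IND-C1", "IND-C2", "IND-C3"}

    def test_direct_without_identical_clone_is_an_error(self, library):
        clones, direct = library
        with pytest.raises(NoGenuineMatchError):
            identify_genuine(clones[3:], direct)

    def test_dominant_haplotype_without_direct(self, library):
        clones, _ = library
        call = identify_genuine(clones, None)
        assert not call.from_direct
        assert set(call.supporting_clones) == {"IND-C1", "IND-C2", "IND-C3"}

    def test_all_unique_without_direct_is_undetermined(self, library):
        clones, _ = library
        with pytest.raises(GenuineUndeterminedError):
            identify_genuine(clones[3:7], None)  # four distinct haplotypes


def _setup(library, use_tree=False, B=100):
    clones, direct = library
    aln = Alignment(clones + [direct])
    dm = distance_matrix(aln)
    call = identify_genuine(clones, direct)
    anchors = sorted(set(call.supporting_clones) | {call.haplotype.id})
    tree = bootstrap_support(aln, B=B, seed=2) if use_tree else None
    cfg = TriageConfig(use_tree_clades=use_tree)
    groups = assign_groups(dm, anchors, tree, cfg, region="other")
    return aln, dm, call, groups, cfg


class TestAssignGroups:
    def test_numts_beyond_cutoff_form_separate_groups(self, library):
        _, _, _, groups, _ = _setup(library)
        assert groups.group_of["IND-C7"] == groups.group_of["IND-C8"] == "B"
        assert groups.group_of["IND-C9"] == "C"  # farther from A than B
        for cid in ("IND-C1", "IND-C4", "IND-C5", "IND-C6"):
            assert groups.group_of[cid] == "A"

    def test_tree_and_distance_evidence_agree_here(self, library):
        _, _, _, groups, _ = _setup(library, use_tree=True)
        assert groups.method == "tree"
        assert groups.group_of["IND-C7"] == "B"
        assert groups.group_of["IND-C4"] == "A"
        assert not groups.conflicted

    def test_all_near_clones_single_group(self, rng):
        base = random_dna(rng, 300)
        recs = [SequenceRecord(f"I-C{i}", base, individual="I") for i in (1, 2)]
        recs.append(SequenceRecord("I-C3", mutate(base, [5]), individual="I"))
        dm = distance_matrix(Alignment(recs))
        groups = assign_groups(dm, ["I-C1", "I-C2"], None,
                               TriageConfig(use_tree_clades=False))
        assert set(groups.group_of.values()) == {"A"}


class TestClassifyClones:
    def test_rule_table(self, library):
        clones, direct = library
        aln, dm, call, groups, cfg = _setup(library)
        report = classify_clones(clones, {"IND": call}, groups, dm, None, cfg)
        labels = dict(zip(report.per_clone.clone_id, report.per_clone.label))
        assert labels["IND-C1"] == "genuine"
        assert labels["IND-C4"] == "pcr_error_variant"  # 1 diff
        assert labels["IND-C5"] == "pcr_error_variant"  # 2 diffs
        assert labels["IND-C6"] == "heteroplasmy"  # 6 diffs, in A
        assert labels["IND-C7"] == labels["IND-C9"] == "numt"

    def test_every_clone_gets_exactly_one_label(self, library):
        clones, _ = library
        aln, dm, call, groups, cfg = _setup(library)
        report = classify_clones(clones, {"IND": call}, groups, dm, None, cfg)
        assert len(report.per_clone) == len(clones)
        assert report.per_clone.label.isin(
            ["genuine", "pcr_error_variant", "heteroplasmy", "numt",
             "ambiguous"]).all()

    def test_undetermined_genuine_makes_clones_ambiguous(self, library):
        clones, _ = library
        aln, dm, call, groups, cfg = _setup(library)
        report = classify_clones(clones, {"IND": None}, groups, dm, None, cfg)
        assert (report.per_clone.label == "ambiguous").all()

    def test_raising_taq_threshold_only_absorbs_boundary_heteroplasmy(self, library):
        clones, _ = library
        aln, dm, call, groups, _ = _setup(library)
        prev_labels = None
        for t in (0, 1, 2):
            cfg = TriageConfig(taq_max_diffs=t)
            rep = classify_clones(clones, {"IND": call}, groups, dm, None, cfg)
            labels = dict(zip(rep.per_clone.clone_id, rep.per_clone.label))
            if prev_labels:
                for cid, lab in prev_labels.items():
                    if lab == "pcr_error_variant":
                        assert labels[cid] == "pcr_error_variant"
                    if lab in ("genuine", "numt"):
                        assert labels[cid] == lab
            prev_labels = labels

    def test_genuine_label_requires_zero_diffs(self, library):
        clones, _ = library
        aln, dm, call, groups, cfg = _setup(library)
        rep = classify_clones(clones, {"IND": call}, groups, dm, None, cfg)
        g = rep.per_clone[rep.per_clone.label == "genuine"]
        assert (g.diffs_events == 0).all()


class TestDivergenceSummary:
    def test_fixed_separation_two_groups(self, rng):
        base = random_dna(rng, 500)
        far = mutate(base, range(0, 500, 10))  # 50 transitions
        recs = [SequenceRecord(f"A-C{i}", base, individual="A") for i in (1, 2)]
        recs += [SequenceRecord(f"B-C{i}", far, individual="B") for i in (1, 2)]
        aln = Alignment(recs)
        dm = distance_matrix(aln)
        groups = assign_groups(dm, ["A-C1", "A-C2"], None,
                               TriageConfig(use_tree_clades=False))
        df = divergence_summary(groups, aln, dm, B=100, seed=0)
        row = df[(df.group_1 == "A") & (df.group_2 == "B")].iloc[0]
        assert row.min_pct == pytest.approx(row.max_pct) == \
            pytest.approx(row.mean_pct)
        expect = dm.get("A-C1", "B-C1") * 100
        assert row.mean_pct == pytest.approx(expect, abs=1e-9)

    def test_mean_equals_cross_cells_mean(self, library):
        aln, dm, call, groups, _ = _setup(library)
        df = divergence_summary(groups, aln, dm, B=100, seed=1)
        row = df[(df.group_1 == "A") & (df.group_2 == "B")].iloc[0]
        labels = dm.labels
        a = groups.members("A")
        b = groups.members("B")
        cells = [dm.get(x, y) for x in a for y in b]
        assert row.mean_pct == pytest.approx(np.mean(cells) * 100, abs=1e-9)
        assert row.n_pairs == len(cells)
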