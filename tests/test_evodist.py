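import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import random_dna
from numtriage.evodist import (DistanceMatrix, SiteDiffSummary, classify_columns,
                               difference_count, distance_matrix, k2p_distance,
                               mean_distance_with_se)
from numtriage.msa import Alignment
from numtriage.seqio import SequenceRecord


class TestClassifyColumns:
    @pytest.mark.parametrize(
        "a,b,L,nP,nQ,indel_cols,indel_events",
        [
            ("ACGT", "ACGT", 4, 0, 0, 0, 0),
            ("ACGT", "GCGT", 4, 1, 0, 0, 0),  # A<->G transition
            ("ACGT", "TCGT", 4, 0, 1, 0, 0),  # A<->T transversion
            ("AC-GT", "ACCGT", 4, 0, 0, 1, 1),
            ("A---T", "ACGGT", 2, 0, 0, 3, 1),  # one 3-column gap run
            ("A--T-C", "ACGTG-", 2, 0, 0, 4, 3),
        ],
    )
    def test_column_tallies(self, a, b, L, nP, nQ, indel_cols, indel_events):
        s = classify_columns(a, b)
        assert (s.compared_sites, s.transitions, s.transversions,
                s.indel_columns, s.indel_events) == \
            (L, nP, nQ, indel_cols, indel_events)

    def test_n_columns_excluded_but_reported(self):
        s = classify_columns("ANGT", "AGGT")
        assert s.compared_sites == 3
        assert s.n_ambiguous == 1

    def test_symmetric_in_arguments(self, rng):
        for _ in range(20):
            a = "".join(rng.choice("ACGTN-") for _ in range(60))
            b = "".join(rng.choice("ACGTN-") for _ in range(60))
            s1, s2 = classify_columns(a, b), classify_columns(b, a)
            assert (s1.compared_sites, s1.transitions, s1.transversions,
                    s1.indel_columns, s1.indel_events) == \
                (s2.compared_sites, s2.transitions, s2.transversions,
                 s2.indel_columns, s2.indel_events)


class TestK2P:
    def test_zero_distance(self):
        assert k2p_distance(SiteDiffSummary(100, 0, 0, 0, 0)).value == 0.0

    def test_transitions_only_closed_form(self):
        # K = -0.5 ln(0.8) for P = 0.1, Q = 0
        r = k2p_distance(SiteDiffSummary(100, 10, 0, 0, 0))
        assert r.value == pytest.approx(-0.5 * math.log(0.8), abs=1e-12)
        assert r.value == pytest.approx(0.11157, abs=5e-6)

    def test_saturation_flagged_not_dropped(self):
        r = k2p_distance(SiteDiffSummary(100, 60, 10, 0, 0))
        assert not r.defined and math.isnan(r.value)
        assert "saturated" in r.reason

    def test_no_comparable_sites(self):
        r = k2p_distance(SiteDiffSummary(0, 0, 0, 0, 0))
        assert not r.defined
        assert r.reason == "no comparable sites"

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(nP=st.integers(0, 40), nQ=st.integers(0, 20))
    def test_k2p_at_least_p_distance(self, nP, nQ):
        r = k2p_distance(SiteDiffSummary(100, nP, nQ, 0, 0))
        if r.defined:
            p = (nP + nQ) / 100
            assert r.value >= p - 1e-12
            if p > 0:
                assert r.value > p


class TestDifferenceCount:
    def test_identical(self):
        assert difference_count("ACGT", "ACGT") == 0

    def test_events_vs_columns(self):
        a = "ACGTACG---T"
        b = "ACTTACGCCCT"  # 1 substitution + one 3-column gap run
        assert difference_count(a, b, "columns") == 4
        assert difference_count(a, b, "events") == 2

    def test_substitutions_counted_same_in_both_modes(self, rng):
        base = random_dna(rng, 200)
        mutated = list(base)
        for pos in rng.sample(range(200), 10):
            mutated[pos] = {"A": "G", "G": "A", "C": "T", "T": "C"}[mutated[pos]]
        assert difference_count(base, "".join(mutated), "events") == 10
        assert difference_count(base, "".join(mutated), "columns") == 10


class TestDistanceMatrix:
    def test_identical_rows_zero_matrix(self):
        aln = Alignment([SequenceRecord(f"s{i}", "ACGTACGT") for i in range(3)])
        dm = distance_matrix(aln)
        assert np.allclose(dm.values, 0)
        assert not dm.undefined_pairs

    def test_matches_elementwise_recomputation(self, rng):
        base = random_dna(rng, 120)
        rows = []
        for k in range(5):
            m = list(base)
            for pos in rng.sample(range(120), 5 * k):
                m[pos] = rng.choice("ACGT".replace(m[pos], ""))
            rows.append("".join(m))
        aln = Alignment([SequenceRecord(f"s{i}", r) for i, r in enumerate(rows)])
        dm = distance_matrix(aln)
        for i in range(5):
            for j in range(i + 1, 5):
                expect = k2p_distance(classify_columns(rows[i], rows[j])).value
                assert dm.values[i, j] == pytest.approx(expect, abs=1e-12)
                assert dm.values[j, i] == dm.values[i, j]

    def test_undefined_pairs_carried_as_sentinels(self):
        aln = Alignment([
            SequenceRecord("a", "AAAAAAAAAA"),
            SequenceRecord("b", "GGGGGGGGGG"),  # all-transition: saturated
            SequenceRecord("c", "AAAAAAAAAA"),
        ])
        dm = distance_matrix(aln)
        assert ("a", "b") in dm.undefined_pairs
        assert math.isnan(dm.get("a", "b"))
        assert dm.get("a", "c") == 0.0

    def test_tsv_round_trip_shape(self, tmp_path):
        aln = Alignment([SequenceRecord(f"s{i}", "ACGTACGT") for i in range(3)])
        p = tmp_path / "d.tsv"
        distance_matrix(aln).to_tsv(p)
        lines = p.read_text().splitlines()
        assert len(lines) == 4 and lines[0].split("\t")[1:] == ["s0", "s1", "s2"]


class TestMeanDistanceWithSE:
    def test_identical_sequences_zero_mean_zero_se(self):
        aln = Alignment([SequenceRecord(f"s{i}", "ACGTACGTACGT") for i in range(3)])
        mean, se = mean_distance_with_se(aln, ["s0", "s1", "s2"], B=100, seed=0)
        assert mean == 0.0 and se == 0.0

    def test_seeded_and_reproducible(self, rng):
        rows = [random_dna(rng, 300) for _ in range(3)]
        aln = Alignment([SequenceRecord(f"s{i}", r) for i, r in enumerate(rows)])
        r1 = mean_distance_with_se(aln, ["s0", "s1", "s2"], B=200, seed=7)
        r2 = mean_distance_with_se(aln, ["s0", "s1", "s2"], B=200, seed=7)
        assert r1 == r2

    def test_se_stable_across_seeds(self, rng):
        # coefficient of variation of the bootstrap SE < 15% at B=1000
        base = random_dna(rng, 800)
        rows = []
        for k in range(3):
            m = list(base)
            for pos in rng.sample(range(800), 8 + 4 * k):
                m[pos] = {"A": "G", "G": "A", "C": "T", "T": "C"}[m[pos]]
            rows.append("".join(m))
        aln = Alignment([SequenceRecord(f"s{i}", r) for i, r in enumerate(rows)])
        ses = [mean_distance_with_se(aln, ["s0", "s1", "s2"], B=1000, seed=s)[1]
               for s in range(5)]
        cv = np.std(ses) / np.mean(ses)
        assert cv < 0.15

    def test_cross_group_mean_matches_cells(self, rng):
        base = random_dna(rng, 200)
        rows = []
        for k in range(4):
            m = list(base)
            for pos in rng.sample(range(200), 6 * k):
                m[pos] = rng.choice("ACGT".replace(m[pos], ""))
            rows.append("".join(m))
        aln = Alignment([SequenceRecord(f"s{i}", r) for i, r in enumerate(rows)])
        dm = distance_matrix(aln)
        mean, _ = mean_distance_with_se(aln, ["s0", "s1"], B=100, seed=0,
                                        labels2=["s2", "s3"])
        cells = [dm.get(a, b) for a in ("s0", "s1") for b in ("s2", "s3")]
        assert mean == pytest.approx(np.mean(cells), abs=1e-12)
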