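import numpy as np
import pytest
from Bio.Align import substitution_matrices
from hypothesis import given, settings, strategies as st

from duxevo._codon import revcomp
from duxevo.io_formats import SeqRecord
from duxevo.synteny_map import (detect_deletion, extract_window, global_align,
                                locate_anchors, AnchorHit)

from oracles import align_score_brute

BLOSUM62 = substitution_matrices.load("BLOSUM62")


class TestGlobalAlign:
    def test_identical_sequences_score_diagonal_sum(self):
        seq = "MKTWQ"
        (a, b), score = global_align(seq, seq)
        assert a == b == seq
        assert score == sum(BLOSUM62[c, c] for c in seq)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            global_align("A", "")

    def test_matches_exhaustive_enumeration_on_short_pairs(self):
        rng = np.random.default_rng(0)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(30):
            a = "".join(aas[rng.integers(0, 20)]
                        for _ in range(rng.integers(1, 6)))
            b = "".join(aas[rng.integers(0, 20)]
                        for _ in range(rng.integers(1, 6)))
            _, score = global_align(a, b)
            assert score == pytest.approx(align_score_brute(a, b))


class TestLocateAnchors:
    def test_planted_anchors_recovered_at_true_span(self, small_sim):
        for (sp, fam), genome in small_sim.genomes.items():
            rec = SeqRecord(f"{sp}|{fam}", genome.sequence())
            anchors = {n: p for n, p in small_sim.anchor_proteins.items()
                       if n.startswith(f"{fam}_")}
            hits = locate_anchors(rec, anchors)
            assert len(hits) == 2
            spans = genome.spans()
            for h in hits:
                name = "anchorL" if h.anchor.endswith("anchorL") else "anchorR"
                s, e = spans[name]
                assert h.start >= s - 3 and h.end <= e
                assert h.strand == "+"
            break

    def test_identity_threshold_is_monotone(self, small_sim):
        (sp, fam), genome = next(iter(small_sim.genomes.items()))
        rec = SeqRecord("w", genome.sequence())
        anchors = {n: p for n, p in small_sim.anchor_proteins.items()
                   if n.startswith(f"{fam}_")}
        lo = locate_anchors(rec, anchors, min_identity=50)
        hi = locate_anchors(rec, anchors, min_identity=100)
        assert len(hi) <= len(lo)

    def test_minus_strand_anchor_reported(self, small_sim):
        (sp, fam), genome = next(iter(small_sim.genomes.items()))
        rec = SeqRecord("w", revcomp(genome.sequence()))
        anchors = {n: p for n, p in small_sim.anchor_proteins.items()
                   if n.startswith(f"{fam}_")}
        hits = locate_anchors(rec, anchors)
        assert hits and all(h.strand == "-" for h in hits)


class TestExtractWindow:
    def _hit(self, name, start, end, strand="+"):
        return AnchorHit(name, "g", start, end, strand, 100.0, 99.0)

    def test_two_anchor_arithmetic(self):
        genome = SeqRecord("g", "A" * 2000)
        w = extract_window([self._hit("a", 100, 200),
                            self._hit("b", 900, 1000)], genome, flank=50)
        assert (w.start, w.end) == (50, 1050)
        assert w.orientation == "same"

    def test_single_anchor_window(self):
        genome = SeqRecord("g", "A" * 2000)
        w = extract_window([self._hit("a", 500, 600)], genome, flank=100)
        assert (w.start, w.end) == (400, 700)

    def test_clipping_at_sequence_bounds(self):
        genome = SeqRecord("g", "A" * 300)
        w = extract_window([self._hit("a", 10, 50)], genome, flank=100)
        assert (w.start, w.end) == (0, 150)

    def test_conflicting_strands_flag_unresolved(self):
        genome = SeqRecord("g", "A" * 2000)
        w = extract_window([self._hit("a", 100, 200, "+"),
                            self._hit("b", 900, 1000, "-")], genome, flank=0)
        assert w.orientation == "unresolved"

    def test_no_anchors_rejected(self):
        with pytest.raises(ValueError):
            extract_window([], SeqRecord("g", "ACGT"), 10)


def _random_dna(n, rng):
    return "".join("ACGT"[rng.integers(0, 4)] for _ in range(n))


class TestDetectDeletion:
    def test_identical_windows_no_deletion(self):
        seq = _random_dna(5000, np.random.default_rng(1))
        assert detect_deletion(seq, seq) == []

    def test_single_planted_excision(self):
        rng = np.random.default_rng(2)
        ref = _random_dna(30_000, rng)
        start, length = 12_000, 10_000
        target = ref[:start] + ref[start + length:]
        dels = detect_deletion(ref, target, min_gap=200)
        assert len(dels) == 1
        (s, e), k = dels[0], 21
        assert abs((e - s) - length) <= 2 * k
        assert abs(s - start) <= 2 * k

    def test_two_excisions_sorted_and_disjoint(self):
        rng = np.random.default_rng(3)
        ref = _random_dna(30_000, rng)
        target = ref[:5000] + ref[7000:20_000] + ref[24_000:]
        dels = detect_deletion(ref, target, min_gap=500)
        assert len(dels) == 2
        assert dels == sorted(dels)
        assert dels[0][1] <= dels[1][0]
        assert sum(e - s for s, e in dels) <= len(ref)

    @settings(max_examples=20, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_self_comparison_always_empty(self, seed):
        seq = _random_dna(2000, np.random.default_rng(seed))
        assert detect_deletion(seq, seq) == []
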