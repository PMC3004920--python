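import numpy as np
import pytest

from duxevo._codon import revcomp
from duxevo.family_sim import HD1_ANCESTOR, _backtranslate, _make_intron, \
    _random_dna, seed_alignment
from duxevo.hd_scan import (HDHit, build_pssm, merge_split_hits, scan,
                            scan_with_halves, six_frame_translate)


@pytest.fixture(scope="module")
def pssm():
    return build_pssm([r.residues for r in seed_alignment()])


def _rng():
    return np.random.default_rng(42)


class TestSixFrameTranslate:
    @pytest.mark.parametrize("seq,frame,expected", [
        ("ATGGCC", 1, "MA"),
        ("TAA", 1, "*"),
        ("ATNGCC", 1, "XA"),
        ("GGCCAT", -1, "MA"),      # reverse complement of ATGGCC
    ])
    def test_examples(self, seq, frame, expected):
        assert six_frame_translate(seq)[frame] == expected

    def test_all_six_frames_present(self):
        frames = six_frame_translate("ATGGCCTTA")
        assert set(frames) == {1, 2, 3, -1, -2, -3}

    def test_too_short(self):
        with pytest.raises(ValueError):
            six_frame_translate("AT")


class TestBuildPssm:
    def test_single_row_small_pseudocount_limit(self):
        row = HD1_ANCESTOR
        p = build_pssm([row], pseudocount=1e-9)
        from duxevo._codon import AA_INDEX
        for i, a in enumerate(row):
            assert p.matrix[i, AA_INDEX[a]] == pytest.approx(np.log2(20), abs=1e-4)

    def test_background_proportional_column_scores_zero(self):
        from duxevo._codon import AA20
        # 20 rows, each residue once per column -> counts match background
        rows = ["".join(AA20[(i + j) % 20] for j in range(60))
                for i in range(20)]
        p = build_pssm(rows, pseudocount=2.0)
        assert np.allclose(p.matrix, 0.0, atol=1e-12)

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            build_pssm([HD1_ANCESTOR, HD1_ANCESTOR[:59]])

    def test_nonpositive_pseudocount_rejected(self):
        with pytest.raises(ValueError, match="pseudocount"):
            build_pssm([HD1_ANCESTOR], pseudocount=0.0)


def _planted_window(rng, intronless=True, intron_len=120):
    """Random 4 kb window with HD1 planted at a known position."""
    hd_nt = _backtranslate(HD1_ANCESTOR, rng)
    if intronless:
        insert = hd_nt
    else:
        sc = 47
        insert = hd_nt[:3 * sc] + _make_intron(intron_len, rng) + hd_nt[3 * sc:]
    left = _random_dna(2000, rng)
    right = _random_dna(2000, rng)
    start = len(left)
    return left + insert + right, start, len(insert)


class TestScan:
    def test_planted_consensus_recovered_at_coordinate(self, pssm):
        seq, start, ln = _planted_window(_rng())
        hits = scan(seq, pssm, 25.0)
        assert hits, "planted homeodomain not found"
        best = max(hits, key=lambda h: h.score)
        assert (best.start, best.end) == (start, start + 180)
        assert best.score == max(h.score for h in hits)

    def test_random_background_has_no_hits(self, pssm):
        seq = _random_dna(10_000, _rng())
        assert scan(seq, pssm, 25.0) == []

    def test_strand_symmetry(self, pssm):
        seq, start, _ = _planted_window(_rng())
        fwd = scan(seq, pssm, 25.0)
        rev = scan(revcomp(seq), pssm, 25.0)
        assert len(fwd) == len(rev)
        L = len(seq)
        fwd_spans = sorted((h.start, h.end, round(h.score, 6)) for h in fwd)
        rev_spans = sorted((L - h.end, L - h.start, round(h.score, 6))
                           for h in rev)
        assert fwd_spans == rev_spans
        assert all(h.strand == "-" for h in rev)

    def test_stop_inside_window_vetoes_hit(self, pssm):
        rng = _rng()
        hd_nt = _backtranslate(HD1_ANCESTOR, rng)
        broken = hd_nt[:90] + "TAA" + hd_nt[93:]
        seq = _random_dna(500, rng) + broken + _random_dna(500, rng)
        fulls = [h for h in scan(seq, pssm, 25.0) if h.span_kind == "full"]
        assert fulls == []


class TestMergeSplitHits:
    def test_planted_split_homeobox_merges(self, pssm):
        seq, start, ln = _planted_window(_rng(), intronless=False)
        hits = scan_with_halves(seq, pssm, 25.0, splice_codon=47)
        merged = merge_split_hits(hits, seq, 47)
        fulls = [h for h in merged if h.span_kind == "full" and h.parts]
        assert len(fulls) == 1
        m = fulls[0]
        assert (m.start, m.end) == (start, start + ln)
        h5, h3 = m.parts
        assert m.score == pytest.approx(h5.score + h3.score)

    def test_no_gt_donor_blocks_merge(self, pssm):
        rng = _rng()
        hd_nt = _backtranslate(HD1_ANCESTOR, rng)
        sc = 47
        bad_intron = "CC" + _random_dna(116, rng) + "AG"
        seq = (_random_dna(1000, rng) + hd_nt[:3 * sc] + bad_intron
               + hd_nt[3 * sc:] + _random_dna(1000, rng))
        hits = scan_with_halves(seq, pssm, 25.0, splice_codon=sc)
        merged = merge_split_hits(hits, seq, sc)
        assert not [h for h in merged if h.parts]

    def test_opposite_strand_partials_never_merge(self):
        h5 = HDHit("w", 1, 100, 241, 0, 50.0, "five_prime_half", 0, 47)
        h3 = HDHit("w", -2, 400, 439, 0, 20.0, "three_prime_half", 47, 60)
        out = merge_split_hits([h5, h3], "A" * 1000, 47)
        assert not [h for h in out if h.parts]

    def test_intron_longer_than_max_blocks_merge(self, pssm):
        seq, _, _ = _planted_window(_rng(), intronless=False, intron_len=500)
        hits = scan_with_halves(seq, pssm, 25.0, splice_codon=47)
        merged = merge_split_hits(hits, seq, 47, max_intron=100)
        assert not [h for h in merged if h.parts]
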