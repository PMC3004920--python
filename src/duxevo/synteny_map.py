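"""Synteny anchoring and deletion mapping.

Conserved neighbouring genes (anchors) are located in a target genome by
six-frame translation plus protein alignment; the candidate window between
or around them is extracted with a flank, and deletions between two
syntenic windows are mapped by co-linear chains of unique exact k-mer
matches — reference intervals left uncovered by the chain are reported as
deletion intervals.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices

from ._codon import revcomp
from .hd_scan import six_frame_translate
from .io_formats import SeqRecord


@dataclass
class AnchorHit:
    anchor: str
    seq_id: str
    start: int
    end: int
    strand: str
    score: float
    identity: float  # percent, 0..100


@dataclass
class SyntenicWindow:
    species: str
    seq_id: str
    start: int
    end: int
    orientation: str                 # same | flipped | unresolved
    anchors: list[AnchorHit] = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        return self.start, self.end


def _aligner(mode: str) -> Align.PairwiseAligner:
    aln = Align.PairwiseAligner()
    aln.mode = mode
    aln.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aln.open_gap_score = -11
    aln.extend_gap_score = -1
    return aln


def global_align(a: str, b: str, gap_open: float = -11,
                 gap_extend: float = -1) -> tuple[tuple[str, str], float]:
    """Optimal global protein alignment under affine gaps (BLOSUM62).

    Returns the first optimal alignment (deterministic traversal order)
    and its score.
    """
    if not a or not b:
        raise ValueError("global_align requires non-empty sequences")
    aln = _aligner("global")
    aln.open_gap_score = gap_open
    aln.extend_gap_score = gap_extend
    alignments = aln.align(a, b)
    best = alignments[0]
    return (str(best[0]), str(best[1])), float(best.score)


def _percent_identity(row_a: str, row_b: str) -> float:
    pairs = [(x, y) for x, y in zip(row_a, row_b) if x != "-" and y != "-"]
    if not pairs:
        return 0.0
    return 100.0 * sum(x == y for x, y in pairs) / len(pairs)


def locate_anchors(genome: SeqRecord, anchor_proteins: dict[str, str],
                   min_identity: float = 50.0) -> list[AnchorHit]:
    """Best placement per anchor via six-frame local alignment."""
    if not anchor_proteins:
        raise ValueError("no anchor proteins supplied")
    frames = six_frame_translate(genome.residues)
    aligner = _aligner("local")
    L = len(genome.residues)
    hits = []
    for name in sorted(anchor_proteins):
        prot = anchor_proteins[name]
        best = None
        for frame in (1, 2, 3, -1, -2, -3):
            target = frames[frame]
            if not target:
                continue
            alns = aligner.align(target, prot)
            if len(alns) == 0:
                continue
            aln = alns[0]
            if best is None or aln.score > best[0]:
                t0 = int(aln.aligned[0][0][0])
                t1 = int(aln.aligned[0][-1][1])
                ident = _percent_identity(str(aln[0]), str(aln[1]))
                best = (float(aln.score), frame, t0, t1, ident)
        if best is None:
            continue
        score, frame, t0, t1, ident = best
        if ident < min_identity:
            continue
        if frame > 0:
            start = (frame - 1) + 3 * t0
            end = (frame - 1) + 3 * t1
            strand = "+"
        else:
            rc_start = (-frame - 1) + 3 * t0
            rc_end = (-frame - 1) + 3 * t1
            start, end = L - rc_end, L - rc_start
            strand = "-"
        hits.append(AnchorHit(anchor=name, seq_id=genome.id, start=start,
                              end=end, strand=strand, score=score,
                              identity=ident))
    return hits


def extract_window(anchor_hits: list[AnchorHit], genome: SeqRecord,
                   flank: int = 20_000, species: str | None = None) -> SyntenicWindow:
    """Window spanning the anchors +/- flank, clipped to the sequence."""
    if not anchor_hits:
        raise ValueError("window extraction requires at least one anchor hit")
    start = max(0, min(h.start for h in anchor_hits) - flank)
    end = min(len(genome.residues), max(h.end for h in anchor_hits) + flank)
    strands = {h.strand for h in anchor_hits}
    if strands == {"+"}:
        orientation = "same"
    elif strands == {"-"}:
        orientation = "flipped"
    else:
        orientation = "unresolved"
    return SyntenicWindow(species=species or genome.id, seq_id=genome.id,
                          start=start, end=end, orientation=orientation,
                          anchors=list(anchor_hits))


def window_sequence(window: SyntenicWindow, genome: SeqRecord) -> str:
    seq = genome.residues[window.start:window.end]
    return revcomp(seq) if window.orientation == "flipped" else seq


# ---------------------------------------------------------------------------
# deletion detection (anchored-gap method)

def _unique_kmers(seq: str, k: int) -> dict[str, int]:
    seen: dict[str, int] = {}
    dupes = set()
    for i in range(len(seq) - k + 1):
        km = seq[i:i + k]
        if km in seen:
            dupes.add(km)
        else:
            seen[km] = i
    for km in dupes:
        del seen[km]
    return seen


def _longest_increasing_chain(pairs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """LIS on the target coordinate of (ref, target) matches sorted by ref."""
    if not pairs:
        return []
    tails: list[int] = []          # smallest tail target value per length
    tails_idx: list[int] = []
    prev = [-1] * len(pairs)
    for i, (_, t) in enumerate(pairs):
        j = bisect_left(tails, t)
        if j == len(tails):
            tails.append(t)
            tails_idx.append(i)
        else:
            tails[j] = t
            tails_idx[j] = i
        prev[i] = tails_idx[j - 1] if j > 0 else -1
    chain = []
    i = tails_idx[-1]
    while i != -1:
        chain.append(pairs[i])
        i = prev[i]
    return chain[::-1]


def detect_deletion(ref_window: str, target_window: str, min_gap: int = 200,
                    k: int = 21) -> list[tuple[int, int]]:
    """Reference intervals absent from the target (deletions), sorted.

    Unique k-mers shared by both windows are chained co-linearly; maximal
    uncovered reference intervals of at least ``min_gap`` bp are reported
    in reference coordinates.
    """
    if not ref_window or not target_window:
        raise ValueError("windows must be non-empty")
    ref_k = _unique_kmers(ref_window, k)
    tgt_k = _unique_kmers(target_window, k)
    pairs = sorted((rpos, tgt_k[km]) for km, rpos in ref_k.items()
                   if km in tgt_k)
    chain = _longest_increasing_chain(pairs)
    if not chain:
        return [(0, len(ref_window))] if len(ref_window) >= min_gap else []
    covered: list[tuple[int, int]] = []
    for rpos, _ in chain:
        iv = (rpos, rpos + k)
        if covered and iv[0] <= covered[-1][1]:
            covered[-1] = (covered[-1][0], max(covered[-1][1], iv[1]))
        else:
            covered.append(iv)
    gaps = []
    for (s0, e0), (s1, e1) in zip(covered, covered[1:]):
        if s1 - e0 >= min_gap:
            gaps.append((e0, s1))
    return gaps


def deletions_to_bed(intervals: list[tuple[int, int]], seq_id: str) -> str:
    lines = [f"{seq_id}\t{s}\t{e}\tdeletion" for s, e in intervals]
    return "\n".join(lines) + ("\n" if lines else "")
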