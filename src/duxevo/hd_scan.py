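"""Homeodomain detection in genomic windows.

Six-frame translation plus a log-odds position-specific scoring matrix
(PSSM) built from a seed alignment of known homeodomains stands in for a
tBLASTn search: it needs no external binary and gives calibrated bit
scores.  Homeodomains are 60 residues; in intron-containing DUX genes each
homeobox is interrupted by an intron at a fixed codon, so the scanner also
searches with the two sub-profiles flanking that splice codon and merges
colinear half-hits across a canonical GT..AG intron.

A stop codon inside a candidate 60-mer vetoes the full-length hit; the
degraded domain is still discoverable through its stop-free half, and the
classifier probes the other side leniently (see ``ortholog_call``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._codon import AA20, AA_INDEX, revcomp, translate
from .io_formats import SeqRecord

HD_LEN = 60
STOP_SCORE = -1e9  # sentinel: any window containing '*' is vetoed


@dataclass
class PSSM:
    """Log-odds profile: ``matrix[i, j]`` is the bit score of residue
    ``AA20[j]`` at column ``i``; ``col_offset`` marks which homeodomain
    columns a sub-profile covers."""

    matrix: np.ndarray            # (ncols, 20) bits
    background: np.ndarray        # (20,) frequencies summing to 1
    pseudocount: float
    col_offset: int = 0

    @property
    def ncols(self) -> int:
        return self.matrix.shape[0]

    def sub(self, start: int, end: int) -> "PSSM":
        return PSSM(self.matrix[start:end], self.background,
                    self.pseudocount, col_offset=self.col_offset + start)


@dataclass
class HDHit:
    """A scored homeodomain match in one reading frame of a window."""

    seq_id: str
    frame: int                 # +1..+3, -1..-3
    start: int                 # genomic, 0-based half-open
    end: int
    protein_offset: int        # position in the frame's translation
    score: float               # bits
    span_kind: str             # full | five_prime_half | three_prime_half
    col_start: int = 0         # homeodomain columns covered [col_start, col_end)
    col_end: int = HD_LEN
    parts: tuple = ()          # for merged hits: the two half hits

    @property
    def strand(self) -> str:
        return "+" if self.frame > 0 else "-"

    @property
    def n_res(self) -> int:
        return self.col_end - self.col_start


def uniform_background() -> np.ndarray:
    return np.full(20, 1.0 / 20.0)


def build_pssm(rows: Sequence[str] | Sequence[SeqRecord],
               pseudocount: float = 1.0,
               background: np.ndarray | None = None,
               length: int = HD_LEN) -> PSSM:
    """Column score(r) = log2(((count_r + pc*bg_r) / (n + pc)) / bg_r)."""
    seqs = [r.residues if isinstance(r, SeqRecord) else r for r in rows]
    if not seqs:
        raise ValueError("empty seed alignment")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if any(len(s) != length for s in seqs):
        raise ValueError(f"ragged seed alignment: all rows must be length {length}")
    if any("-" in s for s in seqs):
        raise ValueError("seed alignment must be gap-free")
    bg = uniform_background() if background is None else np.asarray(background, float)
    if abs(bg.sum() - 1.0) > 1e-9:
        raise ValueError("background frequencies must sum to 1")
    n = len(seqs)
    counts = np.zeros((length, 20))
    for s in seqs:
        for i, a in enumerate(s):
            j = AA_INDEX.get(a)
            if j is not None:
                counts[i, j] += 1
    freq = (counts + pseudocount * bg) / (n + pseudocount)
    matrix = np.log2(freq / bg)
    return PSSM(matrix=matrix, background=bg, pseudocount=pseudocount)


# ---------------------------------------------------------------------------
# translation and scanning

def six_frame_translate(seq: str) -> dict[int, str]:
    """All six conceptual translations, keyed +1..+3 / -1..-3."""
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon")
    rc = revcomp(seq)
    out = {}
    for f in (1, 2, 3):
        out[f] = translate(seq[f - 1:])
        out[-f] = translate(rc[f - 1:])
    return out


def _position_scores(protein: str, pssm: PSSM, lenient: bool = False) -> np.ndarray:
    """Score of the profile at every start position of ``protein``.

    ``lenient`` scores '*' as 0 instead of vetoing the window (used when
    probing for stop-bearing pseudogene domains).
    """
    W = pssm.ncols
    n = len(protein)
    if n < W:
        return np.empty(0)
    idx = np.fromiter((AA_INDEX.get(a, -1) for a in protein), dtype=np.int64,
                      count=n)
    valid = idx >= 0
    safe = np.where(valid, idx, 0)
    nwin = n - W + 1
    scores = np.zeros(nwin)
    for j in range(W):
        col_vals = np.where(valid, pssm.matrix[j][safe], 0.0)
        scores += col_vals[j:j + nwin]
    if not lenient:
        is_stop = np.fromiter((a == "*" for a in protein), dtype=np.int64, count=n)
        cum = np.concatenate([[0], np.cumsum(is_stop)])
        has_stop = (cum[W:] - cum[:-W]) > 0
        scores[has_stop] = STOP_SCORE
    return scores


def score_residues(residues: str, pssm: PSSM, lenient: bool = True) -> float:
    """Score a residue string of exactly the profile's width."""
    if len(residues) != pssm.ncols:
        raise ValueError("residue string length must equal profile width")
    s = _position_scores(residues, pssm, lenient=lenient)
    return float(s[0])


def _frame_to_genomic(frame: int, protein_offset: int, n_res: int,
                      seq_len: int) -> tuple[int, int]:
    span = 3 * n_res
    if frame > 0:
        start = (frame - 1) + 3 * protein_offset
        return start, start + span
    rc_start = (-frame - 1) + 3 * protein_offset
    return seq_len - (rc_start + span), seq_len - rc_start


def _pick_hits(scores: np.ndarray, threshold: float, width: int) -> list[int]:
    """Greedy non-overlapping local maxima above threshold."""
    above = np.flatnonzero(scores >= threshold)
    order = above[np.lexsort((above, -scores[above]))]
    kept: list[int] = []
    for p in order:
        if all(abs(p - q) >= width for q in kept):
            kept.append(int(p))
    return sorted(kept)


def scan(seq: str | SeqRecord, pssm: PSSM, threshold_bits: float = 25.0,
         seq_id: str | None = None, span_kind: str = "full",
         lenient: bool = False) -> list[HDHit]:
    """Scan all six frames with one profile; hits are strand-correct."""
    if isinstance(seq, SeqRecord):
        seq_id = seq_id or seq.id
        seq = seq.residues
    seq_id = seq_id or "window"
    if not np.isfinite(threshold_bits):
        raise ValueError("threshold must be finite")
    hits = []
    frames = six_frame_translate(seq)
    for frame, protein in frames.items():
        scores = _position_scores(protein, pssm, lenient=lenient)
        for p in _pick_hits(scores, threshold_bits, pssm.ncols):
            start, end = _frame_to_genomic(frame, p, pssm.ncols, len(seq))
            hits.append(HDHit(
                seq_id=seq_id, frame=frame, start=start, end=end,
                protein_offset=p, score=float(scores[p]), span_kind=span_kind,
                col_start=pssm.col_offset,
                col_end=pssm.col_offset + pssm.ncols))
    hits.sort(key=lambda h: (h.start, h.frame))
    return hits


def scan_with_halves(seq: str | SeqRecord, pssm: PSSM,
                     threshold_bits: float = 25.0, splice_codon: int = 47,
                     min_half: int = 8, seq_id: str | None = None,
                     half_bits_per_col: float = 1.7) -> list[HDHit]:
    """Full-profile scan plus the two intron-flanking half profiles.

    Half thresholds scale with the number of columns at
    ``half_bits_per_col`` bits each — steeper than the full-length
    threshold because short sub-profiles are far less informative per
    residue (a 13-column half at the full profile's per-column rate would
    fire on random sequence several times per 10 kb).  Halves shorter than
    ``min_half`` residues are not searched (noise floor).
    """
    if not (1 <= splice_codon <= HD_LEN - 1):
        raise ValueError("splice_codon must lie inside the homeodomain")
    hits = scan(seq, pssm, threshold_bits, seq_id=seq_id)
    per_col = max(threshold_bits / HD_LEN, half_bits_per_col)
    if splice_codon >= min_half:
        p5 = pssm.sub(0, splice_codon)
        hits += scan(seq, p5, per_col * p5.ncols, seq_id=seq_id,
                     span_kind="five_prime_half")
    if HD_LEN - splice_codon >= min_half:
        p3 = pssm.sub(splice_codon, HD_LEN)
        hits += scan(seq, p3, per_col * p3.ncols, seq_id=seq_id,
                     span_kind="three_prime_half")
    hits.sort(key=lambda h: (h.start, h.frame, h.span_kind))
    return hits


# ---------------------------------------------------------------------------
# split-hit merging

def merge_split_hits(hits: list[HDHit], seq: str | SeqRecord,
                     splice_codon: int = 47, max_intron: int = 10_000,
                     group_key=None) -> list[HDHit]:
    """Merge colinear 5'/3' half hits separated by a canonical GT..AG intron.

    Unmergeable partials pass through unchanged; the merged hit's score is
    the sum of its parts.  When ``group_key`` is given, only halves with
    equal keys may merge (e.g. halves assigned to the same homeodomain —
    this stops a 5' half from grabbing the 3' half of the *next* domain
    when its own partner fell below threshold).
    """
    if isinstance(seq, SeqRecord):
        seq = seq.residues
    fives = [h for h in hits if h.span_kind == "five_prime_half"]
    threes = [h for h in hits if h.span_kind == "three_prime_half"]
    others = [h for h in hits if h.span_kind == "full"]
    used_three: set[int] = set()
    merged: list[HDHit] = []
    unmerged_fives: list[HDHit] = []
    for h5 in sorted(fives, key=lambda h: h.start):
        best = None
        for i, h3 in enumerate(threes):
            if i in used_three or h3.strand != h5.strand:
                continue
            if group_key is not None and group_key(h5) != group_key(h3):
                continue
            # 5' half must precede 3' half on the coding strand
            if h5.strand == "+":
                intron_len = h3.start - h5.end
                intron = seq[h5.end:h3.start]
            else:
                intron_len = h5.start - h3.end
                intron = revcomp(seq[h3.end:h5.start])
            if intron_len < 4 or intron_len > max_intron:
                continue
            if not (intron.startswith("GT") and intron.endswith("AG")):
                continue
            if best is None or intron_len < best[0]:
                best = (intron_len, i, h3)
        if best is None:
            unmerged_fives.append(h5)
            continue
        _, i, h3 = best
        used_three.add(i)
        merged.append(HDHit(
            seq_id=h5.seq_id, frame=h5.frame,
            start=min(h5.start, h3.start), end=max(h5.end, h3.end),
            protein_offset=h5.protein_offset,
            score=h5.score + h3.score, span_kind="full",
            col_start=0, col_end=HD_LEN, parts=(h5, h3)))
    leftovers = unmerged_fives + [h for i, h in enumerate(threes)
                                  if i not in used_three]
    out = others + merged + leftovers
    out.sort(key=lambda h: (h.start, h.frame))
    return out


def dedup_halves(hits: list[HDHit]) -> list[HDHit]:
    """Drop half hits wholly contained in a full hit on the same strand."""
    fulls = [h for h in hits if h.span_kind == "full"]
    out = []
    for h in hits:
        if h.span_kind != "full" and any(
                f.strand == h.strand and f.start <= h.start and h.end <= f.end
                for f in fulls):
            continue
        out.append(h)
    return out


def hits_to_bed(hits: list[HDHit]) -> str:
    """BED6 export (0-based half-open; score column in bits)."""
    lines = []
    for h in hits:
        lines.append("\t".join([
            h.seq_id, str(h.start), str(h.end),
            f"hd_{h.span_kind}", f"{h.score:.2f}", h.strand]))
    return "\n".join(lines) + ("\n" if lines else "")
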