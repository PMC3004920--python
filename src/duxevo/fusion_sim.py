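"""Fusion of two tandem single-homeobox genes by one deletion.

The model locus carries two identically oriented copies of a two-exon
single-homeobox gene (sDUX-like): exon 1 holds the 5' part of the
homeobox, an intron interrupts the homeobox at the configured splice
codon, and exon 2 holds the 3' part followed by a long open reading
frame.  A single deletion with its left breakpoint in copy 1's exon-2 ORF
(downstream of its homeodomain) and its right breakpoint upstream of
copy 2's homeobox joins the two copies into one candidate
double-homeodomain gene.

With breakpoints drawn uniformly and independently the fused junction is
in frame with probability exactly 1/3 (for interval lengths that are
multiples of 3), independent of the locus geometry — the quantitative
heart of the duplication-by-deletion scenario.  The simulator also
reports whether the fused transcript is stop-free with the second
homeodomain intact, and the length of junction sequence stranded between
the two homeoboxes (the raw material of a new intron 3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._codon import translate
from .family_sim import HD1_ANCESTOR, _backtranslate, _make_intron, _random_dna, \
    _random_protein


@dataclass
class FusionLocusConfig:
    splice_codon: int = 47
    upstream_codons: int = 30        # coding codons in exon 1 before the homeobox
    exon2_len: int = 989             # total exon-2 length in bp (observed mean)
    intron_len: int = 300
    spacer_len: int = 5000
    seed: int = 0


@dataclass
class FusionLocus:
    """Coordinates of the two tandem copies on one strand."""

    seq: str
    # copy 1
    c1_cds_start: int                # start of exon 1 coding
    c1_hd_start: int                 # homeobox 5' part start (exon 1)
    c1_intron: tuple[int, int]
    c1_exon2_start: int              # exon 2 coding start (homeobox 3' part)
    c1_hd_tail_end: int              # end of homeobox part within exon 2
    c1_orf_end: int                  # end of exon 2 ORF (before stop codon)
    # copy 2 (same layout, shifted)
    c2_cds_start: int
    c2_hd_start: int
    c2_intron: tuple[int, int]
    c2_exon2_start: int
    c2_hd_tail_end: int
    c2_orf_end: int

    @property
    def left_region(self) -> tuple[int, int]:
        """Admissible left-breakpoint interval: copy 1 exon-2 ORF after HD."""
        return self.c1_hd_tail_end, self.c1_orf_end

    @property
    def right_region(self) -> tuple[int, int]:
        """Admissible right-breakpoint interval: copy 2 coding before HD."""
        return self.c2_cds_start, self.c2_hd_start


@dataclass
class FusionOutcome:
    left: int
    right: int
    in_frame: bool
    stop_free: bool
    hd2_intact: bool
    new_intron_len: int


@dataclass
class FrameRetentionResult:
    proportion: float
    ci_low: float
    ci_high: float
    n_draws: int
    filters: tuple[str, ...]


def build_locus(cfg: FusionLocusConfig | None = None) -> FusionLocus:
    """Construct the tandem two-copy locus deterministically from the seed."""
    cfg = cfg or FusionLocusConfig()
    rng = np.random.default_rng(cfg.seed)
    sc = cfg.splice_codon
    hd = HD1_ANCESTOR
    orf_codons = (cfg.exon2_len - 3 * (60 - sc)) // 3
    if orf_codons < 3:
        raise ValueError("exon2_len too short for the homeobox tail")

    def one_copy():
        upstream = _backtranslate(_random_protein(cfg.upstream_codons, rng), rng)
        exon1 = upstream + _backtranslate(hd[:sc], rng)
        intron = _make_intron(cfg.intron_len, rng)
        exon2 = (_backtranslate(hd[sc:], rng)
                 + _backtranslate(_random_protein(orf_codons, rng)[1:], rng))
        return upstream, exon1, intron, exon2

    parts = []
    coords = []
    pos = 0
    lead = _random_dna(200, rng)
    parts.append(lead)
    pos += len(lead)
    copy_coords = []
    for copy in range(2):
        upstream, exon1, intron, exon2 = one_copy()
        cds_start = pos
        hd_start = pos + len(upstream)
        parts.append(exon1)
        pos += len(exon1)
        intron_span = (pos, pos + len(intron))
        parts.append(intron)
        pos += len(intron)
        exon2_start = pos
        hd_tail_end = pos + 3 * (60 - sc)
        parts.append(exon2)
        pos += len(exon2)
        orf_end = pos
        parts.append("TAA")
        pos += 3
        copy_coords.append((cds_start, hd_start, intron_span, exon2_start,
                            hd_tail_end, orf_end))
        if copy == 0:
            spacer = _random_dna(cfg.spacer_len, rng)
            parts.append(spacer)
            pos += len(spacer)
    tail = _random_dna(200, rng)
    parts.append(tail)
    (c1s, c1h, c1i, c1e2, c1t, c1o), (c2s, c2h, c2i, c2e2, c2t, c2o) = copy_coords
    return FusionLocus(seq="".join(parts),
                       c1_cds_start=c1s, c1_hd_start=c1h, c1_intron=c1i,
                       c1_exon2_start=c1e2, c1_hd_tail_end=c1t, c1_orf_end=c1o,
                       c2_cds_start=c2s, c2_hd_start=c2h, c2_intron=c2i,
                       c2_exon2_start=c2e2, c2_hd_tail_end=c2t, c2_orf_end=c2o)


def _check_intervals(locus: FusionLocus, left_interval: tuple[int, int],
                     right_interval: tuple[int, int]) -> None:
    l0, l1 = left_interval
    r0, r1 = right_interval
    if not (locus.left_region[0] <= l0 < l1 <= locus.left_region[1]):
        raise ValueError(
            "left interval must lie in copy 1's exon-2 ORF downstream of "
            "its homeobox")
    if not (locus.right_region[0] <= r0 < r1 <= locus.right_region[1]):
        raise ValueError(
            "right interval must lie upstream of copy 2's homeobox (the "
            "fused gene must retain HD2 intact)")


def fused_translation(locus: FusionLocus, left: int, right: int) -> str:
    """Translation of the spliced fused transcript.

    Exons: copy 1 exon 1, then the fused exon (copy 1 exon-2 head + copy 2
    remnant + copy 2 exon 1), then copy 2 exon 2 — with both original
    introns spliced out.
    """
    s = locus.seq
    cds = (s[locus.c1_cds_start:locus.c1_intron[0]]
           + s[locus.c1_exon2_start:left]
           + s[right:locus.c2_intron[0]]
           + s[locus.c2_exon2_start:locus.c2_orf_end + 3])
    return translate(cds)


def random_deletion(locus: FusionLocus, left_interval: tuple[int, int],
                    right_interval: tuple[int, int],
                    rng: np.random.Generator) -> FusionOutcome:
    """One uniform deletion draw; evaluates frame, stops and HD2 integrity."""
    _check_intervals(locus, left_interval, right_interval)
    left = int(rng.integers(left_interval[0], left_interval[1]))
    right = int(rng.integers(right_interval[0], right_interval[1]))
    left_offset = (left - locus.c1_exon2_start) % 3
    right_offset = (right - locus.c2_cds_start) % 3
    in_frame = (left_offset - right_offset) % 3 == 0
    prot = fused_translation(locus, left, right)
    stop_free = "*" not in prot[:-1] and prot.endswith("*")
    hd2_intact = in_frame and stop_free
    new_intron_len = (left - locus.c1_hd_tail_end) + (locus.c2_hd_start - right)
    return FusionOutcome(left=left, right=right, in_frame=in_frame,
                         stop_free=stop_free, hd2_intact=hd2_intact,
                         new_intron_len=new_intron_len)


_FILTER_FIELDS = {"stop_free": "stop_free", "hd2_intact": "hd2_intact"}


def estimate_frame_retention(locus: FusionLocus,
                             left_interval: tuple[int, int] | None = None,
                             right_interval: tuple[int, int] | None = None,
                             n_draws: int = 10_000, seed: int = 0,
                             filters: tuple[str, ...] = ()
                             ) -> FrameRetentionResult:
    """Proportion of uniform deletion draws whose fusion stays in frame
    (optionally also stop-free / HD2-intact), with a normal-approximation
    95% binomial CI."""
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    for f in filters:
        if f not in _FILTER_FIELDS:
            raise ValueError(f"unknown filter {f!r}")
    left_interval = left_interval or locus.left_region
    right_interval = right_interval or locus.right_region
    if left_interval[1] - left_interval[0] < 3 or \
            right_interval[1] - right_interval[0] < 3:
        raise ValueError("breakpoint intervals must be at least 3 bp")
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_draws):
        out = random_deletion(locus, left_interval, right_interval, rng)
        ok = out.in_frame and all(getattr(out, _FILTER_FIELDS[f])
                                  for f in filters)
        hits += ok
    p = hits / n_draws
    half = 1.96 * np.sqrt(p * (1.0 - p) / n_draws)
    return FrameRetentionResult(proportion=p, ci_low=max(0.0, p - half),
                                ci_high=min(1.0, p + half), n_draws=n_draws,
                                filters=tuple(filters))
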