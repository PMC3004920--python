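"""Gene-model assembly and ortholog status classification.

Given homeodomain hits inside a syntenic window, candidate DUX gene models
are assembled (HD1 = 5'-most domain, HD2 downstream) and each model is
classified with the catalogue rules:

* ``intact``      — an uninterrupted ORF spans both homeodomains across the
                    expected exons (split domains joined over canonical
                    GT..AG introns, linker spliced in frame, no stops);
* ``pseudogene``  — a model exists but carries premature stops, frameshifts
                    or missing exons;
* ``unclear``     — an assembly gap (N-run) overlaps the expected locus and
                    no intact model exists;
* ``absent``      — no model and no overlapping gap.

Intronless retrocopies (both domains in one frame with a contiguous
stop-free ORF and no intervening intron) are flagged separately.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from ._codon import revcomp, translate
from .hd_scan import (HD_LEN, HDHit, PSSM, build_pssm, dedup_halves,
                      merge_split_hits, scan_with_halves, score_residues)
from .io_formats import SeqRecord

_GAP_RE = re.compile(r"N{2,}")


# ---------------------------------------------------------------------------
# domain-level assembly

@dataclass
class DomainModel:
    """State of one homeodomain inside a candidate gene model."""

    index: int                     # 1 or 2
    complete: bool = False
    has_stop: bool = False
    frameshift: bool = False
    missing: bool = False          # half or whole domain unaccounted for
    span: tuple[int, int] | None = None
    residues: str = ""
    hits: list[HDHit] = field(default_factory=list)


@dataclass
class GeneModel:
    strand: str
    hd1: DomainModel | None
    hd2: DomainModel | None
    linker_kind: str | None = None       # spliced | contiguous | None
    linker_residues: str = ""
    span: tuple[int, int] | None = None

    @property
    def is_retrocopy(self) -> bool:
        return (self.linker_kind == "contiguous"
                and self.hd1 is not None and self.hd2 is not None
                and self.hd1.complete and self.hd2.complete
                and not (self.hd1.has_stop or self.hd2.has_stop)
                and all(not d.hits or all(not h.parts for h in d.hits)
                        for d in (self.hd1, self.hd2)))


@dataclass
class OrthologCall:
    family: str
    species: str
    status: str                          # intact | pseudogene | unclear | absent
    evidence: set[str] = field(default_factory=set)
    locus: tuple[int, int] | None = None
    copies: int = 0
    retrocopy: bool = False


@dataclass
class CallOptions:
    threshold_bits: float = 25.0
    half_bits_per_col: float = 1.7       # per-column threshold for half profiles
    splice_codon: int = 47
    max_intron: int = 10_000
    max_linker_exon: int = 300           # bp of coding tail searched per side
    min_intron: int = 40
    gap_min: int = 50                    # bp of N to trigger "unclear"
    max_gene_span: int = 8_000           # bp separating candidate array units
    frameshift_margin_bits: float = 25.0  # shifted-frame evidence needed
    # splice-anchored probes search ~50 candidate positions, not a whole
    # window, so they may accept at a fraction of the genome-wide half bar
    anchored_relax: float = 0.6


def domain_profiles(seed_records) -> tuple[PSSM, PSSM, PSSM]:
    """(combined, HD1-specific, HD2-specific) profiles from a seed alignment
    whose record ids end in _HD1 / _HD2."""
    all_rows = [r.residues for r in seed_records]
    hd1 = [r.residues for r in seed_records if r.id.upper().endswith("HD1")]
    hd2 = [r.residues for r in seed_records if r.id.upper().endswith("HD2")]
    combined = build_pssm(all_rows)
    p1 = build_pssm(hd1) if hd1 else combined
    p2 = build_pssm(hd2) if hd2 else combined
    return combined, p1, p2


def _hit_residues(hit: HDHit, seq: str) -> str:
    """Translated residues of a hit (coding orientation)."""
    if hit.parts:
        return "".join(_hit_residues(p, seq) for p in
                       sorted(hit.parts, key=lambda h: h.col_start))
    sub = seq[hit.start:hit.end]
    if hit.strand == "-":
        sub = revcomp(sub)
    return translate(sub)


def assign_domain(hit: HDHit, seq: str, pssm_hd1: PSSM, pssm_hd2: PSSM) -> int:
    """1 or 2, by which domain-specific profile scores the hit higher."""
    res = _hit_residues(hit, seq)
    s1 = score_residues(res, pssm_hd1.sub(hit.col_start, hit.col_end))
    s2 = score_residues(res, pssm_hd2.sub(hit.col_start, hit.col_end))
    return 1 if s1 >= s2 else 2


# ---------------------------------------------------------------------------
# probing for the missing half of a partial domain

def _probe_missing_half(seq: str, present: HDHit, missing_5prime: bool,
                        profile: PSSM, opt: CallOptions,
                        exclude: list[tuple[int, int]] = ()
                        ) -> tuple[str, str, tuple[int, int] | None]:
    """Look for the other half of a partially matched domain.

    Returns (verdict, residues, span) with verdict one of ``present``,
    ``stop`` (half present but interrupted by a stop), ``frameshift``
    (half present out of frame), ``absent``.  Candidate spans overlapping
    ``exclude`` (territory already claimed by the other homeodomain) are
    never accepted.
    """
    W = profile.ncols
    span = 3 * W
    half_thr = max(opt.threshold_bits / HD_LEN, opt.half_bits_per_col) * W

    def excluded(cand: tuple[int, int]) -> bool:
        return any(s < cand[1] and cand[0] < e for s, e in exclude)

    best_splice = None
    if missing_5prime:
        # acceptor ends at present.start; enumerate donors upstream
        a = present.start
        if seq[a - 2:a] == "AG":
            lo = max(span, a - opt.max_intron)
            for d in range(a - opt.min_intron, lo - 1, -1):
                if seq[d:d + 2] != "GT" or excluded((d - span, d)):
                    continue
                region = seq[d - span:d]
                res = translate(region)
                if len(res) != W:
                    continue
                sc = score_residues(res, profile)
                if best_splice is None or sc > best_splice[0]:
                    best_splice = (sc, res, (d - span, d))
    else:
        d = present.end
        if seq[d:d + 2] == "GT":
            hi = min(len(seq) - span, d + opt.max_intron)
            for a in range(d + opt.min_intron, hi):
                if seq[a - 2:a] != "AG" or excluded((a, a + span)):
                    continue
                region = seq[a:a + span]
                res = translate(region)
                if len(res) != W:
                    continue
                sc = score_residues(res, profile)
                if best_splice is None or sc > best_splice[0]:
                    best_splice = (sc, res, (a, a + span))
    if best_splice is not None and best_splice[0] >= opt.anchored_relax * half_thr:
        _, res, found = best_splice
        return ("stop" if "*" in res else "present", res, found)
    # unconstrained lenient probe: any frame offset in the neighbourhood
    if missing_5prime:
        lo = max(0, present.start - opt.max_intron - span)
        neighbourhood = seq[lo:present.start]
        base = lo
    else:
        hi = min(len(seq), present.end + opt.max_intron + span)
        neighbourhood = seq[present.end:hi]
        base = present.end
    best = -np.inf
    best_res = ""
    best_span = None
    for off in range(3):
        prot = translate(neighbourhood[off:])
        if len(prot) < W:
            continue
        from .hd_scan import _position_scores
        sc = _position_scores(prot, profile, lenient=True)
        for p in np.argsort(sc)[::-1][:10]:
            cand = (base + off + 3 * int(p), base + off + 3 * (int(p) + W))
            if excluded(cand):
                continue
            if sc[p] > best:
                best = float(sc[p])
                best_res = prot[p:p + W]
                best_span = cand
            break
    if best >= half_thr:
        return ("stop" if "*" in best_res else "frameshift", best_res,
                best_span)
    return ("absent", "", None)


def _internal_frameshift(seq: str, hit: HDHit, profile: PSSM,
                         opt: CallOptions) -> bool:
    """Shifted-frame scan for a frameshift hidden inside a 'complete' domain.

    A 1-2 bp indel inside an exon leaves part of the domain scoring well in
    the claimed frame and the complementary part scoring well only in a
    shifted frame at the same locus.  For each codon-aligned part of the
    hit, compare per-column profile scores in the claimed frame against the
    two shifted frames; a contiguous segment where a shifted frame wins by
    a large margin (``frameshift_margin_bits``, reachable only when several
    consecutive columns decode better out of frame) betrays the lesion.
    Clean domains essentially never trigger this: the shifted frames decode
    garbage everywhere.
    """
    margin = opt.frameshift_margin_bits
    parts = sorted(hit.parts, key=lambda p: p.col_start) if hit.parts else [hit]
    for p in parts:
        sub = seq[p.start:p.end]
        if p.strand == "-":
            sub = revcomp(sub)
        cols = profile.matrix[p.col_start - profile.col_offset:
                              p.col_end - profile.col_offset]
        base = _column_scores(translate(sub), cols)
        for d in (1, 2):
            alt = _column_scores(translate(sub[d:]), cols)
            n = min(len(base), len(alt))
            if n == 0:
                continue
            diff = alt[:n] - base[:n]
            # maximum-sum contiguous segment (Kadane)
            run = best = 0.0
            for v in diff:
                run = max(0.0, run + v)
                best = max(best, run)
            if best >= margin:
                return True
    return False


def _column_scores(residues: str, cols: np.ndarray) -> np.ndarray:
    from ._codon import AA_INDEX
    n = min(len(residues), len(cols))
    out = np.zeros(n)
    for i in range(n):
        j = AA_INDEX.get(residues[i])
        out[i] = cols[i][j] if j is not None else 0.0
    return out


def _build_domain(index: int, hits: list[HDHit], seq: str, profile: PSSM,
                  opt: CallOptions,
                  exclude: list[tuple[int, int]] = ()) -> DomainModel:
    dm = DomainModel(index=index, hits=hits)
    if not hits:
        dm.missing = True
        return dm
    fulls = [h for h in hits if h.span_kind == "full"]
    if fulls:
        h = max(fulls, key=lambda x: x.score)
        dm.complete = True
        dm.span = (h.start, h.end)
        dm.residues = _hit_residues(h, seq)
        dm.has_stop = "*" in dm.residues
        if _internal_frameshift(seq, h, profile, opt):
            dm.frameshift = True
            dm.complete = False
        return dm
    halves = {h.span_kind: h for h in hits}
    h5 = halves.get("five_prime_half")
    h3 = halves.get("three_prime_half")
    present = h5 or h3
    dm.span = (min(h.start for h in hits), max(h.end for h in hits))
    if h5 is not None and h3 is not None:
        # both halves seen but unmergeable: broken splice or frame change
        r5, r3 = _hit_residues(h5, seq), _hit_residues(h3, seq)
        dm.residues = r5 + r3
        dm.has_stop = "*" in dm.residues
        if (h3.start - h5.end) % 3 != 0:
            dm.frameshift = True
        elif not dm.has_stop:
            dm.frameshift = True   # colinear, in frame, but no splice signal
        return dm
    missing_5prime = h5 is None
    sc = opt.splice_codon
    sub = profile.sub(0, sc) if missing_5prime else profile.sub(sc, HD_LEN)
    verdict, res, found = _probe_missing_half(seq, present, missing_5prime,
                                              sub, opt, exclude=exclude)
    present_res = _hit_residues(present, seq)
    dm.residues = (res + present_res) if missing_5prime else (present_res + res)
    if found is not None:
        dm.span = (min(dm.span[0], found[0]), max(dm.span[1], found[1]))
    if verdict == "present":
        dm.complete = True
        dm.has_stop = "*" in dm.residues
        # the probed half may itself hide a frameshift upstream of the
        # splice site: check both parts in shifted frames
        probe_hit = HDHit(present.seq_id, present.frame, found[0], found[1],
                          0, 0.0, "probe", sub.col_offset,
                          sub.col_offset + sub.ncols)
        composite = HDHit(present.seq_id, present.frame,
                          min(present.start, found[0]),
                          max(present.end, found[1]), 0, 0.0, "full",
                          0, HD_LEN, parts=(present, probe_hit))
        if _internal_frameshift(seq, composite, profile, opt):
            dm.frameshift = True
            dm.complete = False
    elif verdict == "stop":
        dm.has_stop = True
    elif verdict == "frameshift":
        dm.frameshift = True
        dm.has_stop = dm.has_stop or "*" in res
    else:
        dm.missing = True
    return dm


# ---------------------------------------------------------------------------
# linker search between HD1 and HD2

def _find_linker(seq: str, hd1_end: int, hd2_start: int,
                 opt: CallOptions) -> tuple[str, str] | None:
    """An in-frame, stop-free coding path from HD1 end to HD2 start.

    Tries direct readthrough first (retrocopies), then a single spliced
    intron with canonical GT..AG.  Returns (kind, residues) or None.
    """
    gap = hd2_start - hd1_end
    if gap < 0:
        return None
    if gap % 3 == 0:
        res = translate(seq[hd1_end:hd2_start])
        if "*" not in res:
            return ("contiguous", res)
    max_tail = opt.max_linker_exon
    donors = [d for d in range(hd1_end, min(hd2_start - 2, hd1_end + max_tail))
              if seq[d:d + 2] == "GT"]
    acceptors = [a for a in range(max(hd1_end + 2, hd2_start - max_tail),
                                  hd2_start + 1) if seq[a - 2:a] == "AG"]
    for d in donors:
        for a in acceptors:
            intron = a - d
            if intron < opt.min_intron or intron > opt.max_intron:
                continue
            exonic = (d - hd1_end) + (hd2_start - a)
            if exonic % 3 != 0:
                continue
            res = translate(seq[hd1_end:d] + seq[a:hd2_start])
            if "*" not in res:
                return ("spliced", res)
    return None


# ---------------------------------------------------------------------------
# candidate assembly and status calling

def assemble_gene_model(hits: list[HDHit], seq: str, pssm: PSSM,
                        pssm_hd1: PSSM, pssm_hd2: PSSM,
                        opt: CallOptions | None = None,
                        strand: str = "+") -> GeneModel | None:
    """One candidate gene model from the hits of one array unit."""
    opt = opt or CallOptions()
    if not hits:
        return None
    hd1_hits = [h for h in hits if assign_domain(h, seq, pssm_hd1, pssm_hd2) == 1]
    hd2_hits = [h for h in hits if assign_domain(h, seq, pssm_hd1, pssm_hd2) == 2]
    hd1 = _build_domain(1, hd1_hits, seq, pssm_hd1, opt,
                        exclude=[(h.start, h.end) for h in hd2_hits])
    hd2 = _build_domain(2, hd2_hits, seq, pssm_hd2, opt,
                        exclude=[(h.start, h.end) for h in hd1_hits])
    model = GeneModel(strand=strand, hd1=hd1, hd2=hd2)
    spans = [s for s in (hd1.span, hd2.span) if s]
    if spans:
        model.span = (min(s for s, _ in spans), max(e for _, e in spans))
    if (hd1.complete and hd2.complete and not hd1.has_stop
            and not hd2.has_stop and hd1.span and hd2.span):
        link = _find_linker(seq, hd1.span[1], hd2.span[0], opt)
        if link is not None:
            model.linker_kind, model.linker_residues = link
    return model


def _split_units(hits: list[HDHit], seq: str, pssm_hd1: PSSM, pssm_hd2: PSSM,
                 opt: CallOptions) -> list[list[HDHit]]:
    """Partition strand-sorted hits into candidate array units.

    A new unit starts when an HD1-class hit follows an HD2-class hit, or
    when consecutive hits are separated by more than ``max_gene_span``.
    """
    units: list[list[HDHit]] = []
    cur: list[HDHit] = []
    seen_hd2 = False
    last_end = None
    for h in sorted(hits, key=lambda x: x.start):
        dom = assign_domain(h, seq, pssm_hd1, pssm_hd2)
        fresh = (cur and ((dom == 1 and seen_hd2)
                          or (last_end is not None
                              and h.start - last_end > opt.max_gene_span)))
        if fresh:
            units.append(cur)
            cur, seen_hd2 = [], False
        cur.append(h)
        seen_hd2 = seen_hd2 or dom == 2
        last_end = h.end
    if cur:
        units.append(cur)
    return units


def _gap_runs(seq: str, gap_min: int) -> list[tuple[int, int]]:
    return [(m.start(), m.end()) for m in _GAP_RE.finditer(seq)
            if m.end() - m.start() >= gap_min]


def call_status(model: GeneModel | None, window_seq: str,
                expected_span: tuple[int, int] | None = None,
                opt: CallOptions | None = None,
                family: str = "", species: str = "") -> OrthologCall:
    """Classify one candidate (or the absence of one) per the catalogue rules."""
    opt = opt or CallOptions()
    gaps = _gap_runs(window_seq, opt.gap_min)

    def gap_overlaps(span: tuple[int, int] | None) -> bool:
        if span is None:
            return bool(gaps)
        s, e = span
        return any(gs < e and s < ge for gs, ge in gaps)

    if model is None or (model.hd1.missing and model.hd2.missing):
        if gap_overlaps(expected_span):
            return OrthologCall(family, species, "unclear",
                                evidence={"assembly_gap"})
        return OrthologCall(family, species, "absent")

    evidence: set[str] = set()
    for dm in (model.hd1, model.hd2):
        if dm.missing:
            evidence.add("missing_exon")
        if dm.has_stop:
            evidence.add("premature_stop")
        if dm.frameshift:
            evidence.add("frameshift")
        if not dm.complete and not dm.missing and not dm.has_stop \
                and not dm.frameshift:
            evidence.add("missing_exon")
    intact = (model.hd1.complete and model.hd2.complete
              and not evidence and model.linker_kind is not None)
    if intact:
        call = OrthologCall(family, species, "intact", locus=model.span,
                            copies=1, retrocopy=model.is_retrocopy)
        return call
    if (model.hd1.complete and model.hd2.complete and not evidence
            and model.linker_kind is None):
        evidence.add("frameshift")    # ORF discontinuity between the domains
    if evidence <= {"missing_exon"} and gap_overlaps(
            _pad_span(model.span, 2000, len(window_seq))):
        return OrthologCall(family, species, "unclear",
                            evidence=evidence | {"assembly_gap"},
                            locus=model.span)
    return OrthologCall(family, species, "pseudogene", evidence=evidence,
                        locus=model.span, copies=1)


def _pad_span(span: tuple[int, int] | None, pad: int,
              limit: int) -> tuple[int, int] | None:
    if span is None:
        return None
    return max(0, span[0] - pad), min(limit, span[1] + pad)


def detect_retrocopy(hits: list[HDHit], seq: str,
                     opt: CallOptions | None = None) -> tuple[bool, tuple[int, int] | None]:
    """Flag an intronless double-domain copy: two full unsplit hits in one
    frame with a contiguous stop-free ORF covering both."""
    opt = opt or CallOptions()
    fulls = [h for h in hits if h.span_kind == "full" and not h.parts]
    for i, a in enumerate(sorted(fulls, key=lambda h: h.start)):
        for b in sorted(fulls, key=lambda h: h.start)[i + 1:]:
            if a.strand != b.strand:
                continue
            if (b.start - a.end) % 3 != 0 or b.start < a.end:
                continue
            res = translate(seq[a.end:b.start]) if a.strand == "+" else \
                translate(revcomp(seq[a.end:b.start]))
            if "*" in res:
                continue
            return True, (a.start, b.end)
    return False, None


# ---------------------------------------------------------------------------
# window-level driver

@dataclass
class WindowResult:
    strand: str
    seq: str                        # window normalised to the coding strand
    models: list[GeneModel]
    calls: list[OrthologCall]
    family_call: OrthologCall
    retro: bool
    retro_span: tuple[int, int] | None


_STATUS_PRIORITY = {"intact": 3, "pseudogene": 2, "unclear": 1, "absent": 0}


def analyze_window(window_seq: str, seed_records, family: str = "",
                   species: str = "",
                   expected_span: tuple[int, int] | None = None,
                   opt: CallOptions | None = None) -> WindowResult:
    """Scan, assemble and classify everything in one syntenic window.

    The window is normalised to the coding strand first (scanning is
    strand-symmetric, so a reverse-orientation window is re-scanned on its
    reverse complement).
    """
    opt = opt or CallOptions()
    profiles = domain_profiles(seed_records)
    pssm, p1, p2 = profiles
    strand = "+"
    seq = window_seq
    hits = _scan_window(seq, profiles, opt)
    minus = [h for h in hits if h.strand == "-"]
    plus = [h for h in hits if h.strand == "+"]
    if sum(h.score for h in minus) > sum(h.score for h in plus):
        strand = "-"
        seq = revcomp(window_seq)
        hits = _scan_window(seq, profiles, opt)
    hits = [h for h in hits if h.strand == "+"]

    models = []
    calls = []
    for unit in _split_units(hits, seq, p1, p2, opt):
        model = assemble_gene_model(unit, seq, pssm, p1, p2, opt, strand=strand)
        if model is None:
            continue
        models.append(model)
        calls.append(call_status(model, seq, expected_span, opt,
                                 family=family, species=species))
    if not calls:
        family_call = call_status(None, seq, expected_span, opt,
                                  family=family, species=species)
    else:
        best = max(calls, key=lambda c: _STATUS_PRIORITY[c.status])
        n_copies = sum(c.copies for m, c in zip(models, calls)
                       if not m.is_retrocopy)
        family_call = OrthologCall(
            family, species, best.status, evidence=best.evidence,
            locus=best.locus, copies=n_copies, retrocopy=False)
    retro, retro_span = detect_retrocopy(hits, seq, opt)
    family_call.retrocopy = retro
    return WindowResult(strand=strand, seq=seq, models=models, calls=calls,
                        family_call=family_call, retro=retro,
                        retro_span=retro_span)


def domain_nucleotides(model: GeneModel, seq: str) -> str | None:
    """Concatenated HD1+HD2 coding nucleotides (360 bp) of an intact model."""
    if not (model.hd1 and model.hd2 and model.hd1.complete
            and model.hd2.complete):
        return None
    out = []
    for dm in (model.hd1, model.hd2):
        fulls = [h for h in dm.hits if h.span_kind == "full"]
        if not fulls:
            return None
        h = max(fulls, key=lambda x: x.score)
        parts = sorted(h.parts, key=lambda p: p.col_start) if h.parts else [h]
        for p in parts:
            out.append(seq[p.start:p.end])
    nt = "".join(out)
    return nt if len(nt) == 360 else None


def _validate_fulls(hits: list[HDHit], seq: str, pssm: PSSM,
                    opt: CallOptions) -> list[HDHit]:
    """Demote unsplit full hits whose 5' or 3' half fails its own bar.

    A full-profile hit can read straight through a splice junction into a
    (by chance stop-free) intron: the exonic half carries the whole score
    while the other half decodes garbage.  Such a hit is really only
    evidence for one half and is re-labelled accordingly.
    """
    sc = opt.splice_codon
    per_col = max(opt.threshold_bits / HD_LEN, opt.half_bits_per_col)
    relax = opt.anchored_relax
    out = []
    for h in hits:
        if h.span_kind != "full" or h.parts:
            out.append(h)
            continue
        res = _hit_residues(h, seq)
        s5 = score_residues(res[:sc], pssm.sub(0, sc))
        s3 = score_residues(res[sc:], pssm.sub(sc, HD_LEN))
        ok5 = s5 >= relax * per_col * sc
        ok3 = s3 >= relax * per_col * (HD_LEN - sc)
        if ok5 and ok3:
            out.append(h)
            continue
        if ok5:
            span = (h.start, h.start + 3 * sc) if h.strand == "+" else \
                (h.end - 3 * sc, h.end)
            out.append(HDHit(h.seq_id, h.frame, span[0], span[1],
                             h.protein_offset, s5, "five_prime_half", 0, sc))
        elif ok3:
            w3 = HD_LEN - sc
            span = (h.end - 3 * w3, h.end) if h.strand == "+" else \
                (h.start, h.start + 3 * w3)
            out.append(HDHit(h.seq_id, h.frame, span[0], span[1],
                             h.protein_offset, s3, "three_prime_half",
                             sc, HD_LEN))
    return out


def _dedup_overlapping(hits: list[HDHit]) -> list[HDHit]:
    """Collapse same-kind same-strand hits covering the same locus
    (e.g. a demoted full duplicating an existing half): best score wins."""
    kept: list[HDHit] = []
    for h in sorted(hits, key=lambda x: (-x.score, x.start)):
        clash = False
        for k in kept:
            if k.span_kind != h.span_kind or k.strand != h.strand:
                continue
            overlap = min(k.end, h.end) - max(k.start, h.start)
            if overlap > 0.5 * min(k.end - k.start, h.end - h.start):
                clash = True
                break
        if not clash:
            kept.append(h)
    kept.sort(key=lambda h: (h.start, h.frame))
    return kept


def _scan_window(seq: str, profiles: tuple[PSSM, PSSM, PSSM],
                 opt: CallOptions):
    pssm, p1, p2 = profiles
    hits = scan_with_halves(seq, pssm, opt.threshold_bits, opt.splice_codon,
                            half_bits_per_col=opt.half_bits_per_col)
    hits = _dedup_overlapping(_validate_fulls(hits, seq, pssm, opt))
    hits = merge_split_hits(
        hits, seq, opt.splice_codon, opt.max_intron,
        group_key=lambda h: assign_domain(h, seq, p1, p2))
    return dedup_halves(hits)
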