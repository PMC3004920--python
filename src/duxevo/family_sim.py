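"""Synthetic gene-family evolution: ground-truth genomes for the pipeline.

Each family locus is a small genomic window laid out as

    anchorL -- spacer -- DUX gene (5 exons / 4 introns) -- spacer -- anchorR

evolved along a species tree under a substitution-only model (JC69 or K2P).
Lineage-specific discrete events (nonsense mutation, frameshift, exon or
gene deletion, assembly-gap masking, retrotransposition, tandem
duplication) are applied on named branches, and the generator records the
true status of every (species, family) cell so the whole inference chain
can be benchmarked against known answers.

The double-homeobox gene carries homeodomain 1 split across exons 2/3 and
homeodomain 2 split across exons 4/5, with both introns interrupting the
60-codon homeobox at the same configurable codon — the gene architecture
shared by the intron-containing DUX paralogues.  The two homeodomains are
already divergent in the root ancestor, i.e. the domain duplication
predates every speciation in the simulated tree.

Coding segments (DUX exons, anchors) evolve under a nonsense-protected
substitution process: a substitution that would create a stop codon in a
gene the truth set declares intact is locally repaired.  This models
purifying selection against nonsense alleles; without it, "intact" genes
would accumulate spurious stops at realistic divergences and the truth
labels would be meaningless.  Lesions planted by events are frozen against
subsequent reversion.
"""

from __future__ import annotations

import copy
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from ._codon import AA_TO_CODONS, BASES, STOP_CODONS, revcomp, translate
from .io_formats import Feature, SeqRecord, parse_newick, write_fasta, write_gff

# ---------------------------------------------------------------------------
# fixed ancestral proteins
#
# A PRD-class-like homeodomain consensus; HD2 differs from HD1 at 14 fixed
# positions.  The single-domain outgroup carries a third-state residue at
# every one of those 14 positions plus 8 private ones, so it sits at equal
# distance (22 substitutions) from both domain ancestors — the signature
# of a lineage that split before the domain duplication — and roots the
# tree on the edge between the two domain clades.

HD1_ANCESTOR = "QRRSRTTFTAEQLEELEKAFERTHYPDVFAREELARRLNLSEARVQVWFSNRRAKWRREE"
_HD2_SUBS = {2: "K", 7: "S", 11: "D", 17: "R", 22: "N", 27: "I", 31: "K",
             36: "G", 41: "P", 44: "K", 46: "I", 50: "K", 54: "R", 57: "K"}
_OUT_SUBS = {2: "E", 7: "Y", 11: "N", 17: "Q", 22: "S", 27: "L", 31: "D",
             36: "A", 41: "T", 44: "M", 46: "F", 50: "H", 54: "G", 57: "W",
             4: "P", 9: "V", 19: "L", 24: "C", 33: "M", 38: "D", 48: "I",
             58: "D"}


def _apply_subs(seq: str, subs: dict[int, str]) -> str:
    out = list(seq)
    for i, a in subs.items():
        out[i] = a
    return "".join(out)


HD2_ANCESTOR = _apply_subs(HD1_ANCESTOR, _HD2_SUBS)
OUTGROUP_HD = _apply_subs(HD1_ANCESTOR, _OUT_SUBS)

assert len(HD1_ANCESTOR) == 60


def seed_alignment() -> list[SeqRecord]:
    """The ancestral homeodomains, used to seed the scanning profile."""
    return [SeqRecord("ANC_HD1", HD1_ANCESTOR, alphabet="protein"),
            SeqRecord("ANC_HD2", HD2_ANCESTOR, alphabet="protein")]


# ---------------------------------------------------------------------------
# configuration

@dataclass
class Event:
    """A lineage-specific event on one branch of the species tree.

    ``branch`` names either a leaf or a labelled internal node; the event
    applies at the end of the branch subtending that node.
    """

    branch: str
    family: str
    kind: str      # pseudogenize_stop | frameshift | delete_exon | delete_gene
                   # | insert_gap | retrotranspose | tandem_duplicate
    params: dict = field(default_factory=dict)

    _KINDS = ("pseudogenize_stop", "frameshift", "delete_exon", "delete_gene",
              "insert_gap", "retrotranspose", "tandem_duplicate")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")


@dataclass
class FamilySimConfig:
    species_tree: str                        # Newick, lengths in subs/site
    families: list[str] = field(default_factory=lambda: ["DUXA"])
    events: list[Event] = field(default_factory=list)
    seed: int = 0
    substitution_model: str = "JC69"         # JC69 | K2P
    kappa: float = 2.0
    hd_splice_codon: int = 47                # intron position inside the homeobox
    anchor_rate: float = 0.3                 # rate multiplier for anchor genes
    exon_rate: float = 0.5                   # rate multiplier for DUX exons
    spacer_len: int = 2000
    intron_lens: tuple[int, int, int, int] = (400, 500, 634, 550)
    cterm_codons: int = 80
    anchor_codons: int = 100

    def __post_init__(self) -> None:
        if not (1 <= self.hd_splice_codon <= 59):
            raise ValueError("hd_splice_codon must be in [1, 59]")
        if self.substitution_model not in ("JC69", "K2P"):
            raise ValueError("substitution_model must be JC69 or K2P")


# ---------------------------------------------------------------------------
# genome representation

@dataclass
class Segment:
    """One building block of a locus; the genome is their concatenation."""

    name: str          # e.g. "DUXA.exon2", "anchorL", "spacer1"
    kind: str          # exon | intron | anchor | spacer | retrocopy
    seq: str
    gene: str | None = None
    meta: dict = field(default_factory=dict)


class LocusGenome:
    """A family window in one species: an ordered, mutable segment list."""

    def __init__(self, segments: list[Segment]):
        self.segments = segments
        self.warnings: list[str] = []

    def clone(self) -> "LocusGenome":
        g = LocusGenome(copy.deepcopy(self.segments))
        g.warnings = list(self.warnings)
        return g

    def sequence(self) -> str:
        return "".join(s.seq for s in self.segments)

    def spans(self) -> dict[str, tuple[int, int]]:
        out, pos = {}, 0
        for s in self.segments:
            out[s.name] = (pos, pos + len(s.seq))
            pos += len(s.seq)
        return out

    def get(self, name: str) -> Segment:
        for s in self.segments:
            if s.name == name:
                return s
        raise KeyError(name)

    def gene_segments(self, gene: str) -> list[Segment]:
        return [s for s in self.segments if s.gene == gene]

    def index_of(self, name: str) -> int:
        for i, s in enumerate(self.segments):
            if s.name == name:
                return i
        raise KeyError(name)

    def gene_cds(self, gene: str) -> str:
        return "".join(s.seq for s in self.segments
                       if s.gene == gene and s.kind in ("exon", "anchor"))

    def anchor_features(self, seq_id: str) -> list[Feature]:
        feats = []
        for name, (start, end) in self.spans().items():
            seg = self.get(name)
            if seg.kind == "anchor":
                feats.append(Feature(seq_id=seq_id, start=start, end=end,
                                     strand="+", kind="anchor",
                                     attributes={"Name": seg.name}))
        return feats


# ---------------------------------------------------------------------------
# sequence evolution

_B2I = {b: i for i, b in enumerate(BASES)}


def _seq_to_idx(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    idx = np.full(arr.shape, -1, dtype=np.int64)
    for b, i in _B2I.items():
        idx[arr == ord(b)] = i
    return idx


def _idx_to_seq(idx: np.ndarray, template: str) -> str:
    out = list(template)
    for i, v in enumerate(idx):
        if v >= 0:
            out[i] = BASES[v]
    return "".join(out)


def _k2p_matrix(t: float, kappa: float) -> np.ndarray:
    """K2P transition-probability matrix with t in expected subs/site."""
    # rate matrix scaled to mean rate 1: beta*(kappa+2) = 1 per site
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e1 = np.exp(-4.0 * beta * t)
    e2 = np.exp(-2.0 * (alpha + beta) * t)
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2          # transition
    p_tv = 0.25 - 0.25 * e1                     # each transversion
    p_same = 1.0 - p_ts - 2.0 * p_tv
    # base order A C G T; transitions: A<->G, C<->T
    P = np.full((4, 4), 0.0)
    for i in range(4):
        for j in range(4):
            if i == j:
                P[i, j] = p_same
            elif {BASES[i], BASES[j]} in ({"A", "G"}, {"C", "T"}):
                P[i, j] = p_ts
            else:
                P[i, j] = p_tv
    return P


def evolve_sequence(seq: str, t: float, model: str = "JC69",
                    rng: np.random.Generator | None = None,
                    kappa: float = 2.0) -> str:
    """Evolve by substitutions only; length is preserved, N/IUPAC sites inert."""
    if t < 0:
        raise ValueError("branch length must be non-negative")
    if rng is None:
        rng = np.random.default_rng(0)
    if t == 0 or not seq:
        return seq
    idx = _seq_to_idx(seq)
    valid = idx >= 0
    if model == "JC69":
        p = 0.75 * (1.0 - np.exp(-4.0 * t / 3.0))
        hit = (rng.random(len(seq)) < p) & valid
        n_hit = int(hit.sum())
        if n_hit:
            shift = rng.integers(1, 4, size=n_hit)
            idx[hit] = (idx[hit] + shift) % 4
    elif model == "K2P":
        P = _k2p_matrix(t, kappa)
        cum = np.cumsum(P, axis=1)
        u = rng.random(len(seq))
        new = idx.copy()
        for b in range(4):
            mask = valid & (idx == b)
            new[mask] = np.searchsorted(cum[b], u[mask], side="right")
        idx = np.clip(new, 0, 3)
        idx[~valid] = -1
    else:
        raise ValueError(f"unknown model {model!r}")
    return _idx_to_seq(idx, seq)


def _repair_new_stops(parent: str, child: str) -> str:
    """Revert the minimal substitution(s) in any codon that became a stop."""
    out = list(child)
    for c0 in range(0, len(child) - len(child) % 3, 3):
        codon = child[c0:c0 + 3]
        if codon in STOP_CODONS and parent[c0:c0 + 3] not in STOP_CODONS:
            pcod = parent[c0:c0 + 3]
            fixed = None
            for k in range(3):
                if codon[k] != pcod[k]:
                    cand = codon[:k] + pcod[k] + codon[k + 1:]
                    if cand not in STOP_CODONS:
                        fixed = cand
                        break
            out[c0:c0 + 3] = list(fixed if fixed is not None else pcod)
    return "".join(out)


_RATE_BY_KIND = {"exon": "exon_rate", "anchor": "anchor_rate",
                 "retrocopy": "exon_rate"}


def _evolve_genome(genome: LocusGenome, t: float, cfg: FamilySimConfig,
                   rng: np.random.Generator) -> LocusGenome:
    child = genome.clone()
    for seg in child.segments:
        mult = getattr(cfg, _RATE_BY_KIND.get(seg.kind, ""), 1.0)
        evolved = evolve_sequence(seg.seq, t * mult, cfg.substitution_model,
                                  rng, cfg.kappa)
        if seg.kind in ("exon", "anchor", "retrocopy"):
            evolved = _repair_new_stops(seg.seq, evolved)
        frozen = seg.meta.get("frozen", {})
        if frozen:
            ev = list(evolved)
            for pos, motif in frozen.items():
                ev[pos:pos + len(motif)] = list(motif)
            evolved = "".join(ev)
        seg.seq = evolved
    return child


# ---------------------------------------------------------------------------
# ancestral locus construction

def _backtranslate(protein: str, rng: np.random.Generator) -> str:
    codons = []
    for a in protein:
        opts = AA_TO_CODONS[a]
        codons.append(opts[rng.integers(0, len(opts))])
    return "".join(codons)


def _random_protein(n: int, rng: np.random.Generator) -> str:
    aas = "ACDEFGHIKLMNPQRSTVWY"
    return "M" + "".join(aas[rng.integers(0, 20)] for _ in range(n - 1))


def _random_dna(n: int, rng: np.random.Generator) -> str:
    return "".join(BASES[rng.integers(0, 4)] for _ in range(n))


def _make_intron(n: int, rng: np.random.Generator) -> str:
    if n < 6:
        raise ValueError("introns must be at least 6 bp")
    return "GT" + _random_dna(n - 4, rng) + "AG"


def _intron_segment(name: str, n: int, gene: str,
                    rng: np.random.Generator) -> Segment:
    # canonical GT..AG donor/acceptor signals are under selection in any
    # spliced gene; freeze them so divergence does not silently unsplice
    # an "intact" gene
    seq = _make_intron(n, rng)
    return Segment(name, "intron", seq, gene,
                   meta={"frozen": {0: "GT", n - 2: "AG"}})


def make_dux_gene(name: str, cfg: FamilySimConfig,
                  rng: np.random.Generator) -> list[Segment]:
    """Five-exon double-homeobox gene; all exons are codon-aligned (phase 0)."""
    sc = cfg.hd_splice_codon
    exon1_prot = _random_protein(20, rng)
    pre1 = _random_protein(10, rng)[1:]          # 9 linker codons before HD1
    linker_a = _random_protein(16, rng)[1:]      # 15 codons after HD1
    linker_b = _random_protein(16, rng)[1:]      # 15 codons before HD2
    cterm = _random_protein(cfg.cterm_codons + 1, rng)[1:]
    i1, i2, i3, i4 = cfg.intron_lens
    parts = [
        Segment(f"{name}.exon1", "exon", _backtranslate(exon1_prot, rng), name),
        _intron_segment(f"{name}.intron1", i1, name, rng),
        Segment(f"{name}.exon2", "exon",
                _backtranslate(pre1 + HD1_ANCESTOR[:sc], rng), name),
        _intron_segment(f"{name}.intron2", i2, name, rng),
        Segment(f"{name}.exon3", "exon",
                _backtranslate(HD1_ANCESTOR[sc:] + linker_a, rng), name),
        _intron_segment(f"{name}.intron3", i3, name, rng),
        Segment(f"{name}.exon4", "exon",
                _backtranslate(linker_b + HD2_ANCESTOR[:sc], rng), name),
        _intron_segment(f"{name}.intron4", i4, name, rng),
        Segment(f"{name}.exon5", "exon",
                _backtranslate(HD2_ANCESTOR[sc:] + cterm, rng) + "TAA", name),
    ]
    return parts


def build_ancestor(family: str, cfg: FamilySimConfig,
                   rng: np.random.Generator) -> tuple[LocusGenome, dict[str, str]]:
    """Ancestral window plus the anchor proteins used for synteny mapping."""
    anchors = {}
    segs: list[Segment] = []
    for side in ("anchorL", "anchorR"):
        prot = _random_protein(cfg.anchor_codons, rng)
        anchors[f"{family}_{side}"] = prot
    segs.append(Segment("anchorL", "anchor",
                        _backtranslate(anchors[f"{family}_anchorL"], rng) + "TAA",
                        f"{family}_anchorL"))
    segs.append(Segment("spacer1", "spacer", _random_dna(cfg.spacer_len, rng)))
    segs += make_dux_gene(family, cfg, rng)
    segs.append(Segment("spacer2", "spacer", _random_dna(cfg.spacer_len, rng)))
    segs.append(Segment("anchorR", "anchor",
                        _backtranslate(anchors[f"{family}_anchorR"], rng) + "TAA",
                        f"{family}_anchorR"))
    return LocusGenome(segs), anchors


# ---------------------------------------------------------------------------
# events

def apply_event(genome: LocusGenome, event: Event, cfg: FamilySimConfig,
                rng: np.random.Generator) -> LocusGenome:
    """Apply one lineage-specific event in place (returns the same genome)."""
    fam = event.family
    if event.kind == "pseudogenize_stop":
        # default codon 24 sits inside HD2 (after the 15 linker codons of
        # exon 4), mirroring the observed stop-in-HD2 pseudogene pattern
        exon = event.params.get("exon", "exon4")
        codon = int(event.params.get("codon", 24))
        seg = genome.get(f"{fam}.{exon}")
        c0 = 3 * codon
        if c0 + 3 > len(seg.seq):
            raise ValueError(f"codon {codon} outside {seg.name}")
        seg.seq = seg.seq[:c0] + "TAA" + seg.seq[c0 + 3:]
        seg.meta.setdefault("frozen", {})[c0] = "TAA"
    elif event.kind == "frameshift":
        exon = event.params.get("exon", "exon2")
        offset = int(event.params.get("offset", 40))
        seg = genome.get(f"{fam}.{exon}")
        if offset >= len(seg.seq):
            raise ValueError(f"offset {offset} outside {seg.name}")
        seg.seq = seg.seq[:offset] + seg.seq[offset + 1:]
    elif event.kind == "delete_exon":
        exon = event.params.get("exon", "exon3")
        idx = genome.index_of(f"{fam}.{exon}")
        del genome.segments[idx]
    elif event.kind == "delete_gene":
        kept = [s for s in genome.segments if s.gene != fam]
        if len(kept) == len(genome.segments):
            raise ValueError(f"no segments of gene {fam!r} to delete")
        genome.segments = kept
    elif event.kind == "insert_gap":
        length = int(event.params.get("len", 800))
        remaining = length
        started = False
        for seg in genome.segments:
            if seg.gene == fam and seg.kind in ("exon", "intron"):
                if not started and seg.name.endswith("exon1"):
                    continue  # start masking at exon2 so both HDs are covered
                started = True
                n = min(remaining, len(seg.seq))
                seg.seq = "N" * n + seg.seq[n:]
                seg.meta.setdefault("frozen", {})[0] = "N" * n
                remaining -= n
                if remaining <= 0:
                    break
        if not started:
            raise ValueError(f"gene {fam!r} not present for insert_gap")
    elif event.kind == "retrotranspose":
        exons = [s for s in genome.segments
                 if s.gene == fam and s.kind == "exon"]
        if not exons:
            raise ValueError(f"gene {fam!r} not present for retrotranspose")
        cdna = "".join(s.seq for s in exons)
        idx = genome.index_of("spacer2")
        spacer = genome.segments[idx]
        mid = len(spacer.seq) // 2
        left = Segment("spacer2a", "spacer", spacer.seq[:mid])
        right = Segment("spacer2b", "spacer", spacer.seq[mid:])
        retro = Segment(f"{fam}.retro", "retrocopy", cdna, gene=f"{fam}_retro")
        genome.segments[idx:idx + 1] = [left, retro, right]
    elif event.kind == "tandem_duplicate":
        spacer_len = int(event.params.get("spacer_len", 1500))
        gene_segs = [s for s in genome.segments if s.gene == fam]
        if not gene_segs:
            raise ValueError(f"gene {fam!r} not present for tandem_duplicate")
        last = genome.index_of(gene_segs[-1].name)
        dup = []
        for s in gene_segs:
            c = copy.deepcopy(s)
            c.name = s.name.replace(f"{fam}.", f"{fam}_2.")
            c.gene = f"{fam}_2"
            dup.append(c)
        filler = Segment(f"{fam}.dupspacer", "spacer",
                         _random_dna(spacer_len, rng))
        genome.segments[last + 1:last + 1] = [filler] + dup
    return genome


# ---------------------------------------------------------------------------
# simulation along the tree

_TRUTH_PRIORITY = {"absent": 3, "pseudogene": 2, "unclear": 1, "intact": 0}
_EVENT_TO_STATUS = {
    "delete_gene": ("absent", None),
    "pseudogenize_stop": ("pseudogene", "premature_stop"),
    "frameshift": ("pseudogene", "frameshift"),
    "delete_exon": ("pseudogene", "missing_exon"),
    "insert_gap": ("unclear", "assembly_gap"),
}


@dataclass
class TruthSet:
    """Ground truth emitted with every simulation."""

    table: pd.DataFrame              # species, family, status, evidence, ...
    tree: str                        # the species tree actually used (Newick)
    hd_proteins: dict                # (species, family, domain) -> residues
    duplication_predates_speciation: bool = True

    def status(self, species: str, family: str) -> str:
        row = self.table[(self.table.species == species)
                         & (self.table.family == family)]
        return row.status.iloc[0]


@dataclass
class SimResult:
    genomes: dict                    # (species, family) -> LocusGenome
    truth: TruthSet
    anchor_proteins: dict[str, str]  # anchor name -> protein
    seed_records: list[SeqRecord]
    config: FamilySimConfig

    def genome_record(self, species: str, family: str) -> SeqRecord:
        return SeqRecord(id=f"{species}|{family}",
                         residues=self.genomes[(species, family)].sequence())


def _branch_rng(seed: int, family: str, branch: str) -> np.random.Generator:
    tag = zlib.crc32(f"{family}:{branch}".encode()) & 0x7FFFFFFF
    return np.random.default_rng([seed & 0x7FFFFFFF, tag])


def _label_nodes(tree: dendropy.Tree) -> dict[int, str]:
    """Deterministic branch names: taxon/internal labels where present,
    preorder-indexed placeholders otherwise."""
    labels: dict[int, str] = {}
    for i, node in enumerate(tree.preorder_node_iter()):
        if node.taxon is not None:
            labels[id(node)] = node.taxon.label
        elif node.label:
            labels[id(node)] = node.label
        else:
            labels[id(node)] = f"__internal_{i}"
    return labels


def simulate_family(cfg: FamilySimConfig) -> SimResult:
    """Evolve every family's locus along the species tree; fully seeded."""
    tree = parse_newick(cfg.species_tree)
    leaves = [l.taxon.label for l in tree.leaf_node_iter()]
    if not leaves:
        raise ValueError("species tree has no leaves")
    node_labels = _label_nodes(tree)
    known_branches = set(node_labels.values())
    for ev in cfg.events:
        if ev.branch not in known_branches:
            raise ValueError(f"event references unknown branch {ev.branch!r}")
        if ev.family not in cfg.families:
            raise ValueError(f"event references unknown family {ev.family!r}")

    genomes: dict = {}
    events_applied: dict = {}
    anchor_proteins: dict[str, str] = {}

    for family in cfg.families:
        fam_rng = _branch_rng(cfg.seed, family, "__ancestor__")
        ancestor, anchors = build_ancestor(family, cfg, fam_rng)
        anchor_proteins.update(anchors)

        def recurse(node: dendropy.Node, genome: LocusGenome,
                    inherited: list[Event]) -> None:
            label = node_labels[id(node)]
            branch_events = [e for e in cfg.events
                             if e.family == family and e.branch == label]
            t = node.edge.length or 0.0
            rng = _branch_rng(cfg.seed, family, label)
            g = _evolve_genome(genome, t, cfg, rng)
            for ev in branch_events:
                apply_event(g, ev, cfg, rng)
            lineage = inherited + branch_events
            if node.is_leaf():
                genomes[(label, family)] = g
                events_applied[(label, family)] = lineage
            else:
                for child in node.child_nodes():
                    recurse(child, g, lineage)

        root = tree.seed_node
        root_label = node_labels[id(root)]
        root_events = [e for e in cfg.events
                       if e.family == family and e.branch == root_label]
        for ev in root_events:
            apply_event(ancestor, ev, cfg,
                        _branch_rng(cfg.seed, family, root_label))
        for child in root.child_nodes():
            recurse(child, ancestor, root_events)

    truth = _build_truth(cfg, genomes, events_applied)
    return SimResult(genomes=genomes, truth=truth,
                     anchor_proteins=anchor_proteins,
                     seed_records=seed_alignment(), config=cfg)


def _build_truth(cfg: FamilySimConfig, genomes: dict,
                 events_applied: dict) -> TruthSet:
    sc = cfg.hd_splice_codon
    rows = []
    hd_proteins = {}
    for (species, family), genome in sorted(genomes.items()):
        evs = events_applied[(species, family)]
        status, evidence = "intact", set()
        for ev in evs:
            st, evd = _EVENT_TO_STATUS.get(ev.kind, (None, None))
            if st and _TRUTH_PRIORITY[st] > _TRUTH_PRIORITY[status]:
                status = st
            if evd:
                evidence.add(evd)
        if status == "pseudogene":
            evidence.discard("assembly_gap")
        retro = any(ev.kind == "retrotranspose" for ev in evs)
        copies = 0 if status == "absent" else (
            2 if any(ev.kind == "tandem_duplicate" for ev in evs) else 1)
        spans = genome.spans()
        gene_spans = [spans[s.name] for s in genome.gene_segments(family)]
        if gene_spans:
            start = min(s for s, _ in gene_spans)
            end = max(e for _, e in gene_spans)
        else:
            start = end = -1
        if status == "intact":
            hd1, hd2 = _true_domains(genome, family, sc)
            hd_proteins[(species, family, 1)] = hd1
            hd_proteins[(species, family, 2)] = hd2
            cds = genome.gene_cds(family)
            prot = translate(cds)
            if "*" in prot[:-1]:
                genome.warnings.append(
                    f"{species}/{family}: unplanned stop in intact ORF")
                warnings.warn(genome.warnings[-1], stacklevel=2)
        rows.append({"species": species, "family": family, "status": status,
                     "evidence": ",".join(sorted(evidence)) or ".",
                     "start": start, "end": end, "copies": copies,
                     "retrocopy": retro})
    table = pd.DataFrame(rows)
    return TruthSet(table=table, tree=cfg.species_tree, hd_proteins=hd_proteins)


def _true_domains(genome: LocusGenome, family: str, sc: int) -> tuple[str, str]:
    e2 = genome.get(f"{family}.exon2").seq
    e3 = genome.get(f"{family}.exon3").seq
    e4 = genome.get(f"{family}.exon4").seq
    e5 = genome.get(f"{family}.exon5").seq
    hd1 = translate(e2[-3 * sc:] + e3[:3 * (60 - sc)])
    hd2 = translate(e4[-3 * sc:] + e5[:3 * (60 - sc)])
    return hd1, hd2


# ---------------------------------------------------------------------------
# output files

def write_outputs(result: SimResult, outdir: str | Path) -> None:
    """FASTA per species, GFF3 anchor annotations, TSV truth table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    by_species: dict[str, list] = {}
    for (species, family) in sorted(result.genomes):
        by_species.setdefault(species, []).append(family)
    for species, families in by_species.items():
        recs, feats = [], []
        for family in families:
            rec = result.genome_record(species, family)
            recs.append(rec)
            feats += result.genomes[(species, family)].anchor_features(rec.id)
        write_fasta(recs, outdir / f"{species}.fa")
        write_gff(feats, outdir / f"{species}.anchors.gff3")
    result.truth.table.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    write_fasta(result.seed_records, outdir / "hd_seed.fa")
    write_fasta([SeqRecord(n, p, alphabet="protein")
                 for n, p in sorted(result.anchor_proteins.items())],
                outdir / "anchors.fa")


# ---------------------------------------------------------------------------
# codon-level simulator with selection (used for dN/dS benchmarks)

def evolve_codon_sequence(cds: str, t: float, rng: np.random.Generator,
                          omega: float = 1.0) -> str:
    """Evolve a coding sequence with nonsynonymous changes accepted with
    probability ``omega`` (rejection sampling); stop-gains always rejected."""
    if len(cds) % 3:
        raise ValueError("coding sequence length must be a multiple of 3")
    p = 0.75 * (1.0 - np.exp(-4.0 * t / 3.0))
    out = list(cds)
    for i in range(len(cds)):
        if rng.random() >= p:
            continue
        old = out[i]
        if old not in BASES:
            continue
        new = BASES[(("ACGT".index(old)) + rng.integers(1, 4)) % 4]
        c0 = i - i % 3
        codon_old = "".join(out[c0:c0 + 3])
        codon_new = codon_old[:i - c0] + new + codon_old[i - c0 + 1:]
        if codon_new in STOP_CODONS or codon_old in STOP_CODONS:
            continue
        from ._codon import CODON_TO_AA
        syn = CODON_TO_AA[codon_new] == CODON_TO_AA[codon_old]
        if syn or rng.random() < omega:
            out[i] = new
    return "".join(out)
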