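"""Readers and writers for the formats the pipeline consumes.

Coordinate conventions are fixed package-wide: every span held in memory is
0-based half-open; GFF3 on disk keeps its native 1-based inclusive
convention, and the conversion happens exactly once in each direction.
Newick support values, when present, are carried on internal-node labels
(the common dialect emitted by consensus programs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
from Bio import SeqIO

DNA_RESIDUES = frozenset("ACGTRYSWKMBDHVN")
PROTEIN_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX*")
_ALPHABETS = {"dna": DNA_RESIDUES, "protein": PROTEIN_RESIDUES}


@dataclass
class SeqRecord:
    """A named sequence over a declared alphabet (residues kept uppercase)."""

    id: str
    residues: str
    description: str = ""
    alphabet: str = "dna"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record must have a non-empty id")
        if self.alphabet not in _ALPHABETS:
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        self.residues = self.residues.upper()
        if not self.residues:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        bad = set(self.residues) - _ALPHABETS[self.alphabet]
        if bad:
            raise ValueError(
                f"record {self.id!r}: illegal {self.alphabet} residue(s) "
                f"{''.join(sorted(bad))!r}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Feature:
    """A located annotation; ``start``/``end`` are 0-based half-open."""

    seq_id: str
    start: int
    end: int
    strand: str  # '+', '-' or '.'
    kind: str    # gene | exon | anchor | gap
    attributes: dict[str, str] = field(default_factory=dict)

    _STRANDED_KINDS = ("gene", "exon", "anchor")

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"feature {self.seq_id}:{self.start}-{self.end}: "
                "require 0 <= start < end")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"unknown strand symbol {self.strand!r}")
        if self.kind in self._STRANDED_KINDS and self.strand == ".":
            raise ValueError(f"{self.kind} feature requires a defined strand")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path, alphabet: str = "dna") -> list[SeqRecord]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(SeqRecord(id=rec.id, residues=str(rec.seq),
                                 description=desc, alphabet=alphabet))
    return records


def write_fasta(records: list[SeqRecord], path: str | Path,
                width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3

def read_gff(path: str | Path) -> list[Feature]:
    """Read GFF3; disk coordinates (1-based inclusive) become half-open."""
    features = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 columns")
            seq_id, _source, kind, start, end, _score, strand, _phase, attrs = cols
            start_i, end_i = int(start), int(end)
            if end_i < start_i:
                raise ValueError(f"{path}:{lineno}: end < start on disk")
            attributes = {}
            for item in attrs.split(";"):
                item = item.strip()
                if item and "=" in item:
                    k, v = item.split("=", 1)
                    attributes[k] = v
            features.append(Feature(seq_id=seq_id, start=start_i - 1, end=end_i,
                                    strand=strand, kind=kind,
                                    attributes=attributes))
    return features


def write_gff(features: list[Feature], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = ";".join(f"{k}={v}" for k, v in f.attributes.items())
            fh.write("\t".join([
                f.seq_id, "duxevo", f.kind, str(f.start + 1), str(f.end),
                ".", f.strand, ".", attrs or ".",
            ]) + "\n")


# ---------------------------------------------------------------------------
# Newick

def parse_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string; internal-node labels (if any) carry supports."""
    try:
        tree = dendropy.Tree.get(data=text, schema="newick",
                                 preserve_underscores=True,
                                 suppress_internal_node_taxa=True)
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"malformed Newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate leaf label(s): {dupes}")
    return tree


def read_newick(path: str | Path) -> dendropy.Tree:
    """Parse a Newick tree file (same contract as :func:`parse_newick`)."""
    return parse_newick(Path(path).read_text())


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    out = tree.as_string(schema="newick", suppress_rooting=True,
                         unquoted_underscores=True)
    with open(path, "w") as fh:
        fh.write(out)


def newick_string(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True,
                          unquoted_underscores=True).strip()
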