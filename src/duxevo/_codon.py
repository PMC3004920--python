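"""Genetic-code helpers shared across modules.

Standard (NCBI table 1) code; any codon containing an ambiguous base
translates to X, stops to ``*``.
"""

from __future__ import annotations

from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]

#: codon -> one-letter amino acid, stops mapped to '*'
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    CODON_TO_AA[_stop] = "*"

STOP_CODONS = frozenset(_TABLE.stop_codons)
BASES = "ACGT"

#: amino acid -> list of synonymous codons (stops under '*')
AA_TO_CODONS: dict[str, list[str]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    AA_TO_CODONS.setdefault(_aa, []).append(_codon)

AA20 = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA20)}

_COMP = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                      "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")


def revcomp(seq: str) -> str:
    """Reverse complement; IUPAC ambiguity codes are complemented too."""
    return seq.translate(_COMP)[::-1]


def translate(seq: str) -> str:
    """Translate a DNA string codon by codon (trailing partial codon dropped)."""
    n = len(seq) - len(seq) % 3
    return "".join(CODON_TO_AA.get(seq[i:i + 3], "X") for i in range(0, n, 3))


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS
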