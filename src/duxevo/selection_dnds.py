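"""Nei-Gojobori (1986) pathway-counting dN/dS with Jukes-Cantor correction.

Site counting: at each codon position the synonymous fraction is the
number of synonymous single-nucleotide changes divided by the number of
changes that do not create a stop codon; a codon's synonymous site count S
is the sum over its three positions and N = 3 - S.  For a pair of rows the
site counts are averaged.

Difference counting: for a codon pair differing at k positions, the
synonymous/nonsynonymous step counts are averaged over all k! mutational
orderings; orderings passing through a stop codon are excluded.  Should
every ordering be excluded, the codon falls back to counting each changed
position in isolation and is flagged.

Rates: pS = Sd/S and pN = Nd/N are Jukes-Cantor corrected,
d = -(3/4) ln(1 - (4/3) p); omega = dN/dS, reported as 0 when dN = 0 and
as undefined (None) when dS = 0 — never infinity.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._codon import BASES, CODON_TO_AA, STOP_CODONS


@dataclass
class DnDsResult:
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float
    dN: float
    omega: float | None           # None when dS == 0
    n_codons: int
    fallback_codons: int = 0      # codon pairs counted by the unordered fallback
    dropped_codons: int = 0       # gapped codon columns dropped pairwise


def _codon_pairs(a: str, b: str) -> tuple[list[tuple[str, str]], int]:
    if len(a) != len(b):
        raise ValueError("aligned rows must have equal length")
    if len(a) % 3:
        raise ValueError("row length must be a multiple of 3")
    pairs, dropped = [], 0
    for i in range(0, len(a), 3):
        ca, cb = a[i:i + 3], b[i:i + 3]
        if "-" in ca or "-" in cb:
            dropped += 1
            continue
        last = i + 3 == len(a)
        for c in (ca, cb):
            if c in STOP_CODONS and not last:
                raise ValueError(f"internal stop codon {c} at position {i}")
        if ca in STOP_CODONS or cb in STOP_CODONS:
            dropped += 1          # terminal stop: not a comparable codon site
            continue
        pairs.append((ca, cb))
    return pairs, dropped


def count_sites(row: str) -> tuple[float, float]:
    """NG86 synonymous/nonsynonymous site counts for one coding row."""
    S = 0.0
    n_codons = 0
    for i in range(0, len(row) - len(row) % 3, 3):
        codon = row[i:i + 3]
        if "-" in codon:
            continue
        if codon in STOP_CODONS:
            if i + 3 == len(row):
                continue
            raise ValueError(f"internal stop codon at position {i}")
        n_codons += 1
        for pos in range(3):
            syn = 0
            valid = 0
            for base in BASES:
                if base == codon[pos]:
                    continue
                alt = codon[:pos] + base + codon[pos + 1:]
                if alt in STOP_CODONS:
                    continue
                valid += 1
                if CODON_TO_AA[alt] == CODON_TO_AA[codon]:
                    syn += 1
            if valid:
                S += syn / valid
    return S, 3.0 * n_codons - S


def _codon_path_counts(ca: str, cb: str) -> tuple[float, float, bool]:
    """Average (syn, nonsyn) step counts over stop-free orderings.

    Returns (Sd, Nd, used_fallback)."""
    diff = [k for k in range(3) if ca[k] != cb[k]]
    if not diff:
        return 0.0, 0.0, False
    totals = []
    for order in itertools.permutations(diff):
        cur = ca
        syn = nonsyn = 0
        ok = True
        for k in order:
            nxt = cur[:k] + cb[k] + cur[k + 1:]
            if nxt in STOP_CODONS:
                ok = False
                break
            if CODON_TO_AA[nxt] == CODON_TO_AA[cur]:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        if ok:
            totals.append((syn, nonsyn))
    if totals:
        s = sum(t[0] for t in totals) / len(totals)
        n = sum(t[1] for t in totals) / len(totals)
        return s, n, False
    # all orderings pass through a stop: count positions in isolation
    syn = nonsyn = 0
    for k in diff:
        alt = ca[:k] + cb[k] + ca[k + 1:]
        if CODON_TO_AA.get(alt, "X") == CODON_TO_AA[ca]:
            syn += 1
        else:
            nonsyn += 1
    return float(syn), float(nonsyn), True


def count_differences(a_row: str, b_row: str) -> tuple[float, float]:
    """Total NG86 pathway-averaged (Sd, Nd) over an aligned codon pair."""
    pairs, _ = _codon_pairs(a_row, b_row)
    Sd = Nd = 0.0
    for ca, cb in pairs:
        s, n, _ = _codon_path_counts(ca, cb)
        Sd += s
        Nd += n
    return Sd, Nd


def jukes_cantor(p: float) -> float:
    """d = -(3/4) ln(1 - (4/3) p); undefined for p >= 3/4."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= 0.75:
        raise ValueError(f"Jukes-Cantor correction undefined for p={p:.4f} >= 3/4")
    return -0.75 * np.log(1.0 - (4.0 / 3.0) * p)


def dnds_pair(a_row: str, b_row: str) -> DnDsResult:
    """Pairwise NG86 dN/dS with Jukes-Cantor correction."""
    pairs, dropped = _codon_pairs(a_row, b_row)
    if not pairs:
        raise ValueError("no comparable codons in the pair")
    Sa, Na = count_sites("".join(p[0] for p in pairs))
    Sb, Nb = count_sites("".join(p[1] for p in pairs))
    S, N = 0.5 * (Sa + Sb), 0.5 * (Na + Nb)
    Sd = Nd = 0.0
    fallback = 0
    for ca, cb in pairs:
        s, n, fb = _codon_path_counts(ca, cb)
        Sd += s
        Nd += n
        fallback += fb
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS, dN = jukes_cantor(pS), jukes_cantor(pN)
    if dS == 0.0:
        omega = None
    elif dN == 0.0:
        omega = 0.0
    else:
        omega = dN / dS
    return DnDsResult(S=S, N=N, Sd=Sd, Nd=Nd, pS=pS, pN=pN, dS=dS, dN=dN,
                      omega=omega, n_codons=len(pairs),
                      fallback_codons=fallback, dropped_codons=dropped)


def dnds_mean(rows: list[str], labels: list[str] | None = None
              ) -> tuple[float, pd.DataFrame]:
    """Arithmetic mean of pairwise omega over all unordered pairs."""
    if len(rows) < 2:
        raise ValueError("need at least two rows")
    labels = labels or [f"seq{i}" for i in range(len(rows))]
    records = []
    omegas = []
    for (i, a), (j, b) in itertools.combinations(enumerate(rows), 2):
        res = dnds_pair(a, b)
        if res.omega is None:
            raise ValueError(
                f"omega undefined (dS=0) for pair ({labels[i]}, {labels[j]})")
        omegas.append(res.omega)
        records.append({"a": labels[i], "b": labels[j], "S": res.S, "N": res.N,
                        "Sd": res.Sd, "Nd": res.Nd, "pS": res.pS, "pN": res.pN,
                        "dS": res.dS, "dN": res.dN, "omega": res.omega})
    return float(np.mean(omegas)), pd.DataFrame(records)
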