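"""Independent brute-force oracles used by the test suite.

These deliberately re-derive everything from first principles (Biopython's
codon table, exhaustive enumeration) without importing the implementation
modules they check.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Data import CodonTable
from Bio.Align import substitution_matrices

_CT = CodonTable.unambiguous_dna_by_id[1]
_STOPS = set(_CT.stop_codons)
_NT = "ACGT"


def _aa(codon: str) -> str:
    return "*" if codon in _STOPS else _CT.forward_table[codon]


# ---------------------------------------------------------------------------
# NG86 brute force

def ng86_sites_codon(codon: str) -> float:
    """Synonymous site count of one codon by direct enumeration."""
    s = 0.0
    for pos in range(3):
        changes = []
        for base in _NT:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1:]
            if alt in _STOPS:
                continue
            changes.append(_aa(alt) == _aa(codon))
        if changes:
            s += sum(changes) / len(changes)
    return s


def ng86_brute(a: str, b: str) -> tuple[float, float, float, float]:
    """(S, N, Sd, Nd) for an aligned stop-free codon pair, from scratch."""
    assert len(a) == len(b) and len(a) % 3 == 0
    S = N = Sd = Nd = 0.0
    for i in range(0, len(a), 3):
        ca, cb = a[i:i + 3], b[i:i + 3]
        sa, sb = ng86_sites_codon(ca), ng86_sites_codon(cb)
        S += (sa + sb) / 2.0
        N += (3.0 - sa + 3.0 - sb) / 2.0
        diff = [k for k in range(3) if ca[k] != cb[k]]
        if not diff:
            continue
        path_counts = []
        for order in itertools.permutations(diff):
            cur, syn, non, ok = ca, 0, 0, True
            for k in order:
                nxt = cur[:k] + cb[k] + cur[k + 1:]
                if nxt in _STOPS:
                    ok = False
                    break
                if _aa(nxt) == _aa(cur):
                    syn += 1
                else:
                    non += 1
                cur = nxt
            if ok:
                path_counts.append((syn, non))
        if path_counts:
            Sd += np.mean([p[0] for p in path_counts])
            Nd += np.mean([p[1] for p in path_counts])
        else:
            for k in diff:
                alt = ca[:k] + cb[k] + ca[k + 1:]
                if _aa(alt) == _aa(ca):
                    Sd += 1
                else:
                    Nd += 1
    return S, N, Sd, Nd


def random_codon_row(n_codons: int, rng: np.random.Generator) -> str:
    """A stop-free codon row."""
    sense = sorted(set(_CT.forward_table) - _STOPS)
    return "".join(sense[rng.integers(0, len(sense))] for _ in range(n_codons))


def mutate_codon_row(row: str, n_hits: int, rng: np.random.Generator) -> str:
    """Substitute bases at random positions, keeping every codon stop-free."""
    out = list(row)
    tries = 0
    while n_hits > 0 and tries < 10_000:
        tries += 1
        i = int(rng.integers(0, len(out)))
        base = _NT[rng.integers(0, 4)]
        if base == out[i]:
            continue
        old = out[i]
        out[i] = base
        c0 = i - i % 3
        if "".join(out[c0:c0 + 3]) in _STOPS:
            out[i] = old
            continue
        n_hits -= 1
    return "".join(out)


# ---------------------------------------------------------------------------
# exhaustive least-squares topology search

def enumerate_topologies(n_taxa: int):
    """All unrooted binary topologies as edge dicts {(u,v): None}."""
    assert n_taxa >= 3

    def insert(edges: list[tuple[int, int]], leaf: int, nxt: int):
        for k, (a, b) in enumerate(edges):
            rest = edges[:k] + edges[k + 1:]
            yield rest + [(a, nxt), (b, nxt), (leaf, nxt)], nxt + 1

    center = n_taxa
    base = [(0, center), (1, center), (2, center)]
    trees = [(base, center + 1)]
    for leaf in range(3, n_taxa):
        trees = [t for tr, nxt in trees for t in insert(tr, leaf, nxt)]
    return [edges for edges, _ in trees]


def _path_matrix(edges: list[tuple[int, int]], n_taxa: int) -> np.ndarray:
    adj: dict[int, list[tuple[int, int]]] = {}
    for idx, (a, b) in enumerate(edges):
        adj.setdefault(a, []).append((b, idx))
        adj.setdefault(b, []).append((a, idx))
    pairs = list(itertools.combinations(range(n_taxa), 2))
    A = np.zeros((len(pairs), len(edges)))
    for row, (x, y) in enumerate(pairs):
        # DFS path from x to y recording edge indices
        stack = [(x, -1, [])]
        while stack:
            u, parent, path = stack.pop()
            if u == y:
                A[row, path] = 1.0
                break
            for v, idx in adj[u]:
                if v != parent:
                    stack.append((v, u, path + [idx]))
    return A


def ls_best_tree(D: np.ndarray):
    """Exhaustive least-squares: best topology and fitted branch lengths.

    Returns (splits, split->length dict incl. leaf edges, sse).
    """
    n = D.shape[0]
    d = np.array([D[x, y] for x, y in itertools.combinations(range(n), 2)])
    best = None
    for edges in enumerate_topologies(n):
        A = _path_matrix(edges, n)
        b, res, *_ = np.linalg.lstsq(A, d, rcond=None)
        sse = float(np.sum((A @ b - d) ** 2))
        if best is None or sse < best[0] - 1e-12:
            best = (sse, edges, b)
            if sse < 1e-18:
                break
    sse, edges, b = best
    splits = {}
    adj: dict[int, list[tuple[int, int]]] = {}
    for idx, (a, bb) in enumerate(edges):
        adj.setdefault(a, []).append((bb, idx))
        adj.setdefault(bb, []).append((a, idx))
    for idx, (a, bb) in enumerate(edges):
        seen = {a, bb}
        stack, side = [bb], set()
        while stack:
            u = stack.pop()
            if u < n:
                side.add(u)
            for v, _ in adj[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        if 0 in side:
            side = set(range(n)) - side
        splits[frozenset(side)] = float(b[idx])
    return splits, sse


# ---------------------------------------------------------------------------
# exhaustive global alignment (affine gaps, Biopython conventions)

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def align_score_brute(a: str, b: str, gap_open: float = -11,
                      gap_extend: float = -1) -> float:
    """Max global alignment score by enumerating all alignment paths.

    A gap run of length L costs gap_open + (L-1) * gap_extend, matching
    the PairwiseAligner convention.
    """
    best = [-np.inf]

    def rec(i: int, j: int, score: float, state: str):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + _BLOSUM62[a[i], b[j]], "m")
        if i < len(a):
            cost = gap_extend if state == "ga" else gap_open
            rec(i + 1, j, score + cost, "ga")
        if j < len(b):
            cost = gap_extend if state == "gb" else gap_open
            rec(i, j + 1, score + cost, "gb")

    rec(0, 0, 0.0, "none")
    return best[0]
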