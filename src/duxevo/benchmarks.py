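"""Self-contained benchmark experiments over the package's own machinery.

Each function regenerates its inputs from a seed, runs one inference
chain, and returns the measured quantity: frame retention of random
tandem-copy fusions, exact NJ recovery from additive distances, status
recovery of the synthetic catalogue, the domain-duplication-timing rate,
and dN/dS on a quartet evolved under purifying selection.
"""

from __future__ import annotations

import itertools

import dendropy
import numpy as np

from . import fusion_sim
from .family_sim import (OUTGROUP_HD, FamilySimConfig, evolve_codon_sequence,
                         simulate_family)
from .phylo_infer import (CharacterMatrix, DistanceMatrix,
                          classify_duplication, distance_matrix, nj_tree,
                          tree_splits)
from .selection_dnds import dnds_mean


def frame_retention(seed: int, n_draws: int = 10_000,
                    filters: tuple[str, ...] = ()) -> fusion_sim.FrameRetentionResult:
    """In-frame proportion of random fusions on the default tandem locus."""
    locus = fusion_sim.build_locus(fusion_sim.FusionLocusConfig(seed=seed))
    return fusion_sim.estimate_frame_retention(locus, n_draws=n_draws,
                                               seed=seed + 1, filters=filters)


# ---------------------------------------------------------------------------
# NJ on random additive matrices

def random_additive_tree(n_taxa: int, rng: np.random.Generator
                         ) -> tuple[list[str], np.ndarray, set[frozenset]]:
    """A random unrooted binary tree and its exact path-length matrix.

    Branch lengths are uniform on [0.1, 1.0], keeping the matrix safely
    additive and ties impossible almost surely.
    """
    labels = [f"t{i}" for i in range(n_taxa)]
    # adjacency with branch lengths; start from a 3-star, insert leaves
    nxt = n_taxa          # next internal node id
    edges: dict[tuple[int, int], float] = {}

    def add_edge(a, b, w):
        edges[(min(a, b), max(a, b))] = w

    def del_edge(a, b):
        del edges[(min(a, b), max(a, b))]

    def blen():
        return float(rng.uniform(0.1, 1.0))

    center = nxt
    nxt += 1
    for leaf in range(3):
        add_edge(leaf, center, blen())
    for leaf in range(3, n_taxa):
        (a, b), w = list(edges.items())[rng.integers(0, len(edges))]
        del_edge(a, b)
        mid = nxt
        nxt += 1
        add_edge(a, mid, blen())
        add_edge(b, mid, blen())
        add_edge(leaf, mid, blen())
    # path lengths by BFS from each leaf
    adj: dict[int, list[tuple[int, float]]] = {}
    for (a, b), w in edges.items():
        adj.setdefault(a, []).append((b, w))
        adj.setdefault(b, []).append((a, w))
    D = np.zeros((n_taxa, n_taxa))
    for src in range(n_taxa):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for dst in range(n_taxa):
            D[src, dst] = dist[dst]
    splits = _splits_from_adj(adj, n_taxa, labels)
    return labels, D, splits


def _splits_from_adj(adj, n_taxa: int, labels: list[str]) -> set[frozenset]:
    splits = set()
    for (a, bs) in adj.items():
        for b, _ in bs:
            if a < b:
                continue
            # leaves on b's side when edge (a,b) is cut
            seen = {a, b}
            stack = [b]
            side = set()
            while stack:
                u = stack.pop()
                if u < n_taxa:
                    side.add(labels[u])
                for v, _ in adj[u]:
                    if v not in seen:
                        seen.add(v)
                        stack.append(v)
            if 1 < len(side) < n_taxa - 1:
                ref = labels[0]
                full = frozenset(labels)
                splits.add(full - frozenset(side) if ref in side
                           else frozenset(side))
    return splits


def nj_recovery(seed: int, n_matrices: int = 100,
                sizes: tuple[int, ...] = (4, 5, 6, 7, 8)) -> float:
    """Fraction of random additive matrices whose NJ tree matches the
    generating tree exactly (topology and branch lengths to 1e-6)."""
    rng = np.random.default_rng(seed)
    ok = 0
    for i in range(n_matrices):
        n = sizes[i % len(sizes)]
        labels, D, true_splits = random_additive_tree(n, rng)
        tree = nj_tree(DistanceMatrix(labels, D))
        if tree_splits(tree) != true_splits:
            continue
        # additive => NJ path lengths reproduce the input distances
        leaf = {l.taxon.label: l for l in tree.leaf_node_iter()}
        pdm = tree.phylogenetic_distance_matrix()
        good = True
        for x, y in itertools.combinations(range(n), 2):
            d = pdm.distance(leaf[labels[x]].taxon, leaf[labels[y]].taxon)
            if abs(d - D[x, y]) > 1e-6:
                good = False
                break
        ok += good
    return ok / n_matrices


# ---------------------------------------------------------------------------
# status recovery and duplication timing

def status_recovery(seed: int):
    """Full-pipeline catalogue accuracy on the default synthetic benchmark."""
    from .pipeline_cli import RunConfig, run_pipeline
    report = run_pipeline(RunConfig(seed=seed))
    return report


#: compact 4-species tree for the timing experiment (max pairwise 0.24)
TIMING_TREE = "((sp1:0.06,sp2:0.06)ab:0.04,(sp3:0.08,sp4:0.08)cd:0.02);"


def duplication_timing_rate(seed: int, n_runs: int = 100) -> float:
    """Rate at which individual-domain NJ trees recover a pre-speciation
    domain duplication on families simulated with exactly that history."""
    hits = 0
    for i in range(n_runs):
        cfg = FamilySimConfig(species_tree=TIMING_TREE, families=["DUX"],
                              seed=(seed * 10_007 + i) % (2 ** 31))
        sim = simulate_family(cfg)
        labels, rows, domain_labels = [], [], {}
        for (species, family, dom), prot in sorted(sim.truth.hd_proteins.items()):
            label = f"{family}_{species}_HD{dom}"
            labels.append(label)
            rows.append(prot)
            domain_labels[label] = (f"{family}_{species}", dom)
        labels.append("outgroup")
        rows.append(OUTGROUP_HD)
        matrix = CharacterMatrix(labels, rows, mode="individual")
        tree = nj_tree(distance_matrix(matrix, "poisson"))
        verdict = classify_duplication(tree, domain_labels, "outgroup")
        hits += verdict == "pre_speciation"
    return hits / n_runs


# ---------------------------------------------------------------------------
# dN/dS under purifying selection

def purifying_quartet(seed: int, omega: float = 0.3, n_codons: int = 200,
                      t: float = 0.4) -> tuple[float, float]:
    """Evolve a 4-tip star from one ancestor with nonsynonymous changes
    accepted at probability ``omega``; return (mean NG86 omega, target)."""
    rng = np.random.default_rng(seed)
    from .family_sim import _backtranslate, _random_protein
    anc = _backtranslate(_random_protein(n_codons + 1, rng)[1:], rng)
    tips = [evolve_codon_sequence(anc, t, rng, omega=omega) for _ in range(4)]
    mean_omega, _ = dnds_mean(tips, [f"tip{i}" for i in range(4)])
    return mean_omega, omega
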