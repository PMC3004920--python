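"""Homeodomain phylogenetics: distances, neighbor joining, bootstrap
majority-rule consensus, and the domain-duplication-timing test.

Character matrices come in two flavours mirroring the two published tree
variants: concatenated (HD1+HD2, 120 residues per taxon) and individual
(60 residues, taxa of the form ``gene_HD1`` / ``gene_HD2``).  Trees are
inferred by neighbor joining on p- or Poisson-corrected protein distances
with pairwise deletion of undefined columns; bootstrap support is the
percentage of column-resampled replicates containing each bipartition,
the consensus keeps bipartitions above 50%, and branch lengths are refit
on the consensus topology from the original matrix by non-negative least
squares.

The duplication-timing test asks whether, on a tree rooted at an
outgroup, the first homeodomains of all genes form one clade and the
second homeodomains another (domain duplication before speciation /
gene divergence) or each gene's two domains are sisters (duplication
after), reporting ``unresolved`` for polytomies or weakly supported
configurations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.optimize import nnls

from .io_formats import SeqRecord

HD_LEN = 60
UNDEFINED = set("-X*?")


@dataclass
class CharacterMatrix:
    labels: list[str]
    rows: list[str]
    mode: str = "individual"          # concatenated | individual

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.rows):
            raise ValueError("labels and rows differ in length")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate taxon labels")
        want = 120 if self.mode == "concatenated" else 60
        for lab, row in zip(self.labels, self.rows):
            if len(row) != want:
                raise ValueError(
                    f"row {lab!r} has length {len(row)}, expected {want} "
                    f"for mode {self.mode!r}")

    @property
    def n_taxa(self) -> int:
        return len(self.labels)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    def resample_columns(self, rng: np.random.Generator) -> "CharacterMatrix":
        cols = rng.integers(0, self.n_cols, size=self.n_cols)
        rows = ["".join(r[c] for c in cols) for r in self.rows]
        return CharacterMatrix(list(self.labels), rows, mode=self.mode)


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.all(np.isfinite(v)):
            raise ValueError("distance matrix entries must be finite")
        self.values = v


def concatenate_domains(hd1: str, hd2: str) -> str:
    """HD1 followed by HD2: the 120-residue concatenated character row."""
    if len(hd1) != HD_LEN or len(hd2) != HD_LEN:
        raise ValueError("both domain rows must be exactly 60 residues")
    return hd1 + hd2


def matrix_from_records(records: list[SeqRecord],
                        mode: str = "individual") -> CharacterMatrix:
    return CharacterMatrix([r.id for r in records],
                           [r.residues for r in records], mode=mode)


# ---------------------------------------------------------------------------
# distances

def distance_matrix(matrix: CharacterMatrix,
                    correction: str = "poisson") -> DistanceMatrix:
    """Pairwise p- or Poisson-corrected distances with pairwise deletion."""
    if matrix.n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    if correction not in ("p", "poisson"):
        raise ValueError("correction must be 'p' or 'poisson'")
    n = matrix.n_taxa
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = matrix.rows[i], matrix.rows[j]
            pairs = [(x, y) for x, y in zip(a, b)
                     if x not in UNDEFINED and y not in UNDEFINED]
            if not pairs:
                raise ValueError(
                    f"no mutually defined columns between "
                    f"{matrix.labels[i]!r} and {matrix.labels[j]!r}")
            p = sum(x != y for x, y in pairs) / len(pairs)
            if correction == "p":
                d = p
            else:
                if p >= 1.0:
                    raise ValueError(
                        f"Poisson distance undefined at p=1 for pair "
                        f"({matrix.labels[i]!r}, {matrix.labels[j]!r})")
                d = -np.log(1.0 - p)
            D[i, j] = D[j, i] = d
    return DistanceMatrix(list(matrix.labels), D)


# ---------------------------------------------------------------------------
# neighbor joining

def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Canonical neighbor joining; negative branch lengths clamped to 0,
    ties broken by the smallest original-taxon-index pair."""
    n = len(dm.labels)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    taxa = dendropy.TaxonNamespace(dm.labels)
    nodes = []
    for lab in dm.labels:
        node = dendropy.Node(taxon=taxa.get_taxon(lab))
        nodes.append(node)
    min_idx = list(range(n))           # smallest original index per cluster
    D = dm.values.astype(float).copy()
    active = list(range(n))

    def pick_pair() -> tuple[int, int]:
        r = len(active)
        R = {i: sum(D[i, k] for k in active if k != i) for i in active}
        best = None
        for i, j in itertools.combinations(sorted(active,
                                                  key=lambda x: min_idx[x]), 2):
            q = (r - 2) * D[i, j] - R[i] - R[j]
            key = (q, min(min_idx[i], min_idx[j]), max(min_idx[i], min_idx[j]))
            if best is None or q < best[0][0] - 1e-12 or (
                    abs(q - best[0][0]) <= 1e-12 and key[1:] < best[0][1:]):
                best = (key, (i, j))
        return best[1]

    next_slot = n
    D = np.pad(D, ((0, n - 2), (0, n - 2)))
    nodes += [None] * (n - 2)
    min_idx += [0] * (n - 2)
    while len(active) > 3:
        r = len(active)
        i, j = pick_pair()
        Ri = sum(D[i, k] for k in active if k != i)
        Rj = sum(D[j, k] for k in active if k != j)
        bi = 0.5 * D[i, j] + (Ri - Rj) / (2.0 * (r - 2))
        bj = D[i, j] - bi
        bi, bj = max(bi, 0.0), max(bj, 0.0)
        u = dendropy.Node()
        u.add_child(nodes[i])
        nodes[i].edge.length = bi
        u.add_child(nodes[j])
        nodes[j].edge.length = bj
        for k in active:
            if k in (i, j):
                continue
            D[next_slot, k] = D[k, next_slot] = 0.5 * (D[i, k] + D[j, k]
                                                       - D[i, j])
        nodes[next_slot] = u
        min_idx[next_slot] = min(min_idx[i], min_idx[j])
        active = [k for k in active if k not in (i, j)] + [next_slot]
        next_slot += 1

    a, b, c = sorted(active, key=lambda x: min_idx[x])
    root = dendropy.Node()
    for x, (y, z) in zip((a, b, c), ((b, c), (a, c), (a, b))):
        bl = 0.5 * (D[x, y] + D[x, z] - D[y, z])
        root.add_child(nodes[x])
        nodes[x].edge.length = max(bl, 0.0)
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# splits, consensus, supports

def tree_splits(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions as the leaf-label side not containing the
    lexicographically smallest taxon (an orientation-free encoding)."""
    labels = sorted(l.taxon.label for l in tree.leaf_node_iter())
    ref = labels[0]
    all_set = frozenset(labels)
    splits = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node is tree.seed_node:
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        side = all_set - below if ref in below else below
        if 1 < len(side) < len(labels) - 1:
            splits.add(side)
    return splits


def _tree_from_splits(labels: list[str], splits: list[tuple[frozenset, float]],
                      taxa: dendropy.TaxonNamespace) -> dendropy.Tree:
    """Greedy refinement of a star tree by mutually compatible splits."""
    root = dendropy.Node()
    leaf_nodes = {}
    for lab in labels:
        node = dendropy.Node(taxon=taxa.get_taxon(lab))
        root.add_child(node)
        leaf_nodes[lab] = node
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    tree.is_rooted = False
    for side, support in sorted(splits, key=lambda s: (-s[1], sorted(s[0]))):
        # find the node whose children cover the split side
        groups: dict[dendropy.Node, list[dendropy.Node]] = {}
        for lab in side:
            # climb to the highest ancestor fully inside the side
            anc = leaf_nodes[lab]
            while anc.parent_node is not None and frozenset(
                    l.taxon.label for l in anc.parent_node.leaf_iter()) <= side:
                anc = anc.parent_node
            groups.setdefault(anc.parent_node, []).append(anc)
        if len(groups) != 1:
            continue  # incompatible with current tree (cannot happen >50%)
        parent, children = next(iter(groups.items()))
        children = list(dict.fromkeys(children))
        covered = frozenset(l.taxon.label for ch in children
                            for l in ch.leaf_iter())
        if covered != frozenset(side) or len(children) == len(parent.child_nodes()):
            continue
        new = dendropy.Node()
        new.support = support
        for ch in children:
            parent.remove_child(ch)
            new.add_child(ch)
        parent.add_child(new)
    return tree


def _fit_branch_lengths(tree: dendropy.Tree, dm: DistanceMatrix) -> None:
    """Non-negative least-squares branch lengths from pairwise distances."""
    edges = [e for e in tree.preorder_edge_iter() if e.head_node is not tree.seed_node]
    eindex = {id(e): k for k, e in enumerate(edges)}
    leaves = {l.taxon.label: l for l in tree.leaf_node_iter()}
    pos = {lab: i for i, lab in enumerate(dm.labels)}

    def path_edges(a: dendropy.Node, b: dendropy.Node) -> list[int]:
        anc_a = {}
        node, depth = a, 0
        while node is not None:
            anc_a[id(node)] = depth
            node = node.parent_node
            depth += 1
        path = []
        node = b
        while id(node) not in anc_a:
            path.append(eindex[id(node.edge)])
            node = node.parent_node
        meet = node
        node = a
        while node is not meet:
            path.append(eindex[id(node.edge)])
            node = node.parent_node
        return path

    rows, d = [], []
    labs = list(dm.labels)
    for x, y in itertools.combinations(labs, 2):
        row = np.zeros(len(edges))
        for k in path_edges(leaves[x], leaves[y]):
            row[k] = 1.0
        rows.append(row)
        d.append(dm.values[pos[x], pos[y]])
    A = np.vstack(rows)
    b, _ = nnls(A, np.asarray(d))
    for e, val in zip(edges, b):
        e.length = float(val)


def bootstrap_consensus(matrix: CharacterMatrix, n_reps: int = 100,
                        seed: int = 0, method: str = "poisson",
                        min_freq: float = 0.5) -> dendropy.Tree:
    """Column-resampled NJ bootstrap with majority-rule consensus.

    Support on each internal node is the percentage of replicates whose
    tree contains that bipartition; consensus branch lengths are refit on
    the original matrix.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    for _ in range(n_reps):
        rep = matrix.resample_columns(rng)
        tree = nj_tree(distance_matrix(rep, method))
        for s in tree_splits(tree):
            counts[s] = counts.get(s, 0) + 1
    keep = [(s, 100.0 * c / n_reps) for s, c in counts.items()
            if c / n_reps > min_freq]
    taxa = dendropy.TaxonNamespace(matrix.labels)
    tree = _tree_from_splits(list(matrix.labels), keep, taxa)
    _fit_branch_lengths(tree, distance_matrix(matrix, method))
    for node in tree.preorder_node_iter():
        if not node.is_leaf() and hasattr(node, "support"):
            node.label = f"{node.support:g}"
    return tree


# ---------------------------------------------------------------------------
# duplication-timing classification

def classify_duplication(tree: dendropy.Tree,
                         domain_labels: dict[str, tuple[str, int]],
                         outgroup: str,
                         support_floor: float = 70.0) -> str:
    """``pre_speciation``, ``post_speciation`` or ``unresolved``.

    ``domain_labels`` maps taxon label -> (gene, domain index 1|2).  The
    tree is rooted at ``outgroup`` for evaluation.  A configuration only
    counts if its defining nodes carry no support value or support at or
    above ``support_floor``.
    """
    tree = tree.clone(depth=1)
    leaves = {l.taxon.label: l for l in tree.leaf_node_iter()}
    if outgroup not in leaves:
        raise ValueError(f"outgroup {outgroup!r} not in tree")
    for lab in domain_labels:
        if lab not in leaves:
            raise ValueError(f"taxon {lab!r} not in tree")
    og = leaves[outgroup]
    tree.reroot_at_edge(og.edge, update_bipartitions=False)
    leaves = {l.taxon.label: l for l in tree.leaf_node_iter()}

    genes = sorted({g for g, _ in domain_labels.values()})
    hd = {d: frozenset(lab for lab, (g, dom) in domain_labels.items()
                       if dom == d) for d in (1, 2)}
    if len(genes) < 2 or not hd[1] or not hd[2]:
        raise ValueError("need at least two genes with both domains")

    def supported_clade(target: frozenset[str]) -> bool:
        for node in tree.preorder_node_iter():
            if node.is_leaf():
                continue
            below = frozenset(l.taxon.label for l in node.leaf_iter())
            if below == target:
                sup = getattr(node, "support", None)
                if sup is None and node.label:
                    try:
                        sup = float(node.label)
                    except ValueError:
                        sup = None
                return sup is None or sup >= support_floor
        return False

    if supported_clade(hd[1]) and supported_clade(hd[2]):
        return "pre_speciation"
    if all(supported_clade(frozenset(
            lab for lab, (g, _) in domain_labels.items() if g == gene))
            for gene in genes):
        return "post_speciation"
    return "unresolved"
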