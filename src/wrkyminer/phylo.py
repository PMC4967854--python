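"""Pairwise domain distances, neighbor-joining, bootstrap supports and
clade-based subgroup assignment.

The agglomeration itself is implemented here; dendropy supplies the tree data
structure and Newick serialization.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("distances must be finite")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0):
            raise ValueError("diagonal must be zero")
        if (self.d < -1e-12).any():
            raise ValueError("distances must be non-negative")


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def p_distance_aligned(a: str, b: str) -> float:
    """Mismatch fraction over columns where both sequences have a residue."""
    pairs = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
    if not pairs:
        return 1.0
    return sum(x != y for x, y in pairs) / len(pairs)


def pairwise_distances(seqs: dict[str, str] | list[str]) -> DistanceMatrix:
    """Global-alignment p-distances (BLOSUM62, gap open 10 / extend 0.5)."""
    if isinstance(seqs, list):
        seqs = {f"s{i}": s for i, s in enumerate(seqs)}
    labels = list(seqs)
    if len(labels) < 2:
        raise ValueError("need at least two sequences")
    if any(len(seqs[l]) == 0 for l in labels):
        raise ValueError("zero-length sequence")
    aligner = _aligner()
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = seqs[labels[i]], seqs[labels[j]]
            if a == b:
                continue
            aln = aligner.align(a, b)[0]
            sa, sb = str(aln[0]), str(aln[1])
            d[i, j] = d[j, i] = p_distance_aligned(sa, sb)
    return DistanceMatrix(labels=labels, d=d)


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    Ties on the Q criterion resolve to the lexicographically lowest
    (label-index) pair. Negative branch lengths are clamped to zero with the
    deficit moved to the sibling edge, preserving total tree length.
    """
    n0 = len(dm.labels)
    if n0 < 2:
        raise ValueError("need at least two taxa")
    taxa = dendropy.TaxonNamespace(dm.labels)
    tree = dendropy.Tree(taxon_namespace=taxa)

    nodes: list[dendropy.Node] = []
    for label in dm.labels:
        node = dendropy.Node(taxon=taxa.get_taxon(label))
        nodes.append(node)
    index = list(range(n0))          # active row index -> original position
    d = dm.d.copy()

    active = list(range(n0))         # positions into nodes
    dist = {(i, j): d[i, j] for i in range(n0) for j in range(n0)}

    def get(i: int, j: int) -> float:
        return dist[(i, j)] if i <= j else dist[(j, i)]

    def put(i: int, j: int, value: float) -> None:
        dist[(min(i, j), max(i, j))] = value

    next_id = n0
    while len(active) > 2:
        m = len(active)
        r = {i: sum(get(i, k) for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * get(i, j) - r[i] - r[j]
                key = (q, i, j)
                if best is None or key < best:
                    best = key
        _, i, j = best
        dij = get(i, j)
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        parent = dendropy.Node()
        ni, nj = nodes[i], nodes[j]
        parent.add_child(ni)
        parent.add_child(nj)
        ni.edge.length = li
        nj.edge.length = lj
        nodes.append(parent)
        u = next_id
        next_id += 1
        for k in active:
            if k in (i, j):
                continue
            put(u, k, 0.5 * (get(i, k) + get(j, k) - dij))
        active = [k for k in active if k not in (i, j)] + [u]

    i, j = active
    dij = max(get(i, j), 0.0)   # reduced distances can go negative off-additivity
    ni, nj = nodes[i], nodes[j]
    if ni.is_leaf() and nj.is_leaf():
        root = dendropy.Node()
        root.add_child(ni)
        root.add_child(nj)
        ni.edge.length = dij
        nj.edge.length = 0.0
    else:
        if ni.is_leaf():            # root at the internal node
            ni, nj = nj, ni
        root = ni
        root.add_child(nj)
        nj.edge.length = dij
    tree.seed_node = root
    tree.is_rooted = False
    tree.update_taxon_namespace()
    return tree


def tree_length(tree: dendropy.Tree) -> float:
    return sum(e.length or 0.0 for e in tree.edges())


def bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial splits as canonical leaf-label sets (smaller side, ties by sort)."""
    all_labels = frozenset(t.label for t in tree.taxon_namespace)
    splits = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        other = all_labels - below
        if len(below) < 2 or len(other) < 2:
            continue
        canon = min(below, other, key=lambda s: (len(s), tuple(sorted(s))))
        splits.add(canon)
    return splits


def _resampled_distances(alignment: dict[str, str], cols: np.ndarray) -> DistanceMatrix:
    labels = list(alignment)
    n = len(labels)
    mat = np.array([list(alignment[l]) for l in labels])
    sub = mat[:, cols]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = sub[i], sub[j]
            ok = (a != "-") & (b != "-")
            d[i, j] = d[j, i] = (a[ok] != b[ok]).mean() if ok.any() else 1.0
    return DistanceMatrix(labels=labels, d=d)


def bootstrap_support(alignment: dict[str, str], replicates: int = 1000,
                      seed: int = 0) -> dendropy.Tree:
    """NJ tree from an aligned residue matrix with bootstrap edge supports.

    Columns are resampled with replacement ``replicates`` times; support of an
    internal edge is the fraction of replicate trees containing the same
    bipartition, stored as the internal node label.
    """
    if replicates < 1:
        raise ValueError("need at least one bootstrap replicate")
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise ValueError("alignment rows must have equal length")
    n_cols = lengths.pop()
    rng = np.random.default_rng(seed)

    main = nj_tree(_resampled_distances(alignment, np.arange(n_cols)))
    counts: dict[frozenset[str], int] = {}
    for _ in range(replicates):
        cols = rng.integers(0, n_cols, size=n_cols)
        rep_tree = nj_tree(_resampled_distances(alignment, cols))
        for split in bipartitions(rep_tree):
            counts[split] = counts.get(split, 0) + 1

    all_labels = frozenset(alignment)
    for node in main.preorder_node_iter():
        if node is main.seed_node or node.is_leaf():
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        other = all_labels - below
        if len(below) < 2 or len(other) < 2:
            continue
        canon = min(below, other, key=lambda s: (len(s), tuple(sorted(s))))
        node.label = f"{counts.get(canon, 0) / replicates:.3f}"
    return main


def to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick",
                          suppress_rooting=True,
                          suppress_internal_node_labels=False).strip()


def from_newick(text: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=text, schema="newick")


def assign_subgroup(tree: dendropy.Tree,
                    refs: dict[str, str]) -> dict[str, str]:
    """Label each non-reference leaf from clade context.

    A leaf takes the label of the smallest clade containing it whose
    reference leaves all share one subgroup; if no such clade exists, the
    majority label of its 3 nearest reference leaves by path length.
    """
    if not refs:
        raise ValueError("need at least one reference leaf per subgroup")
    pdm = tree.phylogenetic_distance_matrix()
    leaf_nodes = {l.taxon.label: l for l in tree.leaf_node_iter()}
    out: dict[str, str] = {}
    for label, node in leaf_nodes.items():
        if label in refs:
            out[label] = refs[label]
            continue
        assigned = None
        anc = node.parent_node
        while anc is not None:
            ref_labels = {refs[l.taxon.label] for l in anc.leaf_iter()
                          if l.taxon.label in refs}
            if len(ref_labels) == 1:
                assigned = ref_labels.pop()
                break
            if len(ref_labels) > 1:
                break
            anc = anc.parent_node
        if assigned is None:
            dists = sorted(
                (pdm.patristic_distance(node.taxon,
                                        leaf_nodes[r].taxon), r)
                for r in refs if r in leaf_nodes)
            nearest = [refs[r] for _, r in dists[:3]]
            assigned = max(sorted(set(nearest)), key=nearest.count)
        out[label] = assigned
    return out
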