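"""Independent reference implementations used to verify the package.

Everything here is deliberately naive: explicit graphs, exhaustive
enumeration, closed forms. Nothing imports the implementation under test.
"""

from __future__ import annotations

import itertools

import numpy as np


def random_additive_tree(n_leaves: int, rng: np.random.Generator):
    """Random unrooted binary tree with positive branch lengths.

    Returns (adjacency dict node -> {neighbor: length}, leaf labels).
    Leaves are "L0".."L{n-1}"; internal nodes are integers.
    """
    labels = [f"L{i}" for i in range(n_leaves)]
    adj: dict = {}

    def connect(a, b, w):
        adj.setdefault(a, {})[b] = w
        adj.setdefault(b, {})[a] = w

    def disconnect(a, b):
        del adj[a][b]
        del adj[b][a]

    lengths = iter(rng.uniform(0.5, 2.0, size=4 * n_leaves))
    if n_leaves == 2:
        connect(labels[0], labels[1], next(lengths))
        return adj, labels
    center = 0
    for leaf in labels[:3]:
        connect(center, leaf, next(lengths))
    next_internal = 1
    for leaf in labels[3:]:
        edges = [(a, b) for a in adj for b in adj[a] if str(a) < str(b)]
        a, b = edges[rng.integers(len(edges))]
        w = adj[a][b]
        disconnect(a, b)
        mid = next_internal
        next_internal += 1
        connect(a, mid, w / 2)
        connect(mid, b, w / 2)
        connect(mid, leaf, next(lengths))
    return adj, labels


def path_lengths(adj: dict, labels: list[str]) -> np.ndarray:
    """All-pairs leaf distances by breadth-first traversal."""
    n = len(labels)
    d = np.zeros((n, n))
    for i, src in enumerate(labels):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj[u].items():
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for j, dst in enumerate(labels):
            d[i, j] = dist[dst]
    return d


def tree_bipartitions(adj: dict, labels: list[str]) -> set[frozenset[str]]:
    """Non-trivial splits of an unrooted tree given as an adjacency map."""
    leafset = set(labels)
    splits = set()
    for a in adj:
        for b in adj[a]:
            side = set()
            stack = [a]
            seen = {a, b}
            while stack:
                u = stack.pop()
                if u in leafset:
                    side.add(u)
                for v in adj[u]:
                    if v not in seen:
                        seen.add(v)
                        stack.append(v)
            if 2 <= len(side) <= len(labels) - 2:
                canon = min(frozenset(side), frozenset(leafset - side),
                            key=lambda s: (len(s), tuple(sorted(s))))
                splits.add(canon)
    return splits


QUARTET_TOPOLOGIES = (((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2)))


def best_quartet_split(d: np.ndarray) -> tuple[tuple[int, int], tuple[int, int]]:
    """Exhaustive least-squares fit over the three unrooted 4-taxon topologies."""
    best, best_rss = None, np.inf
    pairs = list(itertools.combinations(range(4), 2))
    for (p, q), (r, s) in QUARTET_TOPOLOGIES:
        # design matrix: pendant edges e0..e3 plus internal edge e4
        rows, y = [], []
        for i, j in pairs:
            row = [0.0] * 5
            row[i] = row[j] = 1.0
            same = ({i, j} == {p, q}) or ({i, j} == {r, s})
            if not same:
                row[4] = 1.0
            rows.append(row)
            y.append(d[i, j])
        coef, rss, *_ = np.linalg.lstsq(np.array(rows), np.array(y), rcond=None)
        resid = float(np.sum((np.array(rows) @ coef - np.array(y)) ** 2))
        if resid < best_rss - 1e-12:
            best_rss, best = resid, ((p, q), (r, s))
    return best


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) by exhaustive enumeration of all C(N, n) draws."""
    universe = list(range(N))
    hits = 0
    total = 0
    for draw in itertools.combinations(universe, n):
        total += 1
        if sum(1 for g in draw if g < K) >= k:
            hits += 1
    return hits / total


def bh_stepup(pvals: list[float]) -> list[float]:
    """Benjamini–Hochberg adjusted p-values, computed by hand."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, pvals[i] * m / rank_from_top)
        adjusted[i] = running
    return adjusted


def pooled_t_pvalue(x: list[float], y: list[float]) -> float:
    """Two-sample equal-variance t-test p-value from the closed form."""
    from scipy.stats import t as tdist
    nx, ny = len(x), len(y)
    mx, my = np.mean(x), np.mean(y)
    sp2 = (np.sum((np.array(x) - mx) ** 2) + np.sum((np.array(y) - my) ** 2)) \
        / (nx + ny - 2)
    tstat = (mx - my) / np.sqrt(sp2 * (1 / nx + 1 / ny))
    return 2 * tdist.sf(abs(tstat), nx + ny - 2)


def iupac_match_bruteforce(seq: str, pattern: str) -> list[int]:
    """Regex lookahead matcher, independent of the per-position scanner."""
    import re
    classes = {
        "A": "A", "C": "C", "G": "G", "T": "T", "R": "[AG]", "Y": "[CT]",
        "S": "[CG]", "W": "[AT]", "K": "[GT]", "M": "[AC]", "B": "[CGT]",
        "D": "[AGT]", "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
    }
    rx = re.compile("(?=(" + "".join(classes[c] for c in pattern) + "))")
    return [m.start() for m in rx.finditer(seq)]
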