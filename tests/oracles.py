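"""Independent oracle implementations used by the test-suite.

Everything here is deliberately naive (per-site loops, exhaustive
enumeration, direct formulas) and shares no code path with the package's
implementations it checks.
"""

from __future__ import annotations

import itertools
from fractions import Fraction

import numpy as np

AA = "ACDEFGHIKLMNPQRSTVWY"
STANDARD = set(AA)


def naive_p_distance(row_a: str, row_b: str) -> tuple[float, int] | None:
    """Per-site counting loop; None when no comparable columns exist."""
    mismatches = 0
    n_sites = 0
    for x, y in zip(row_a, row_b):
        if x in STANDARD and y in STANDARD:
            n_sites += 1
            if x != y:
                mismatches += 1
    if n_sites == 0:
        return None
    return mismatches / n_sites, n_sites


def naive_distance_matrix(rows: dict[str, str]) -> np.ndarray:
    taxa = list(rows)
    n = len(taxa)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            res = naive_p_distance(rows[taxa[i]], rows[taxa[j]])
            out[i, j] = np.nan if res is None else res[0]
    return out


def random_alignment(
    rng: np.random.Generator, n_taxa: int = 10, n_cols: int = 60, gap_frac: float = 0.1
) -> dict[str, str]:
    rows = {}
    for t in range(n_taxa):
        chars = [AA[c] for c in rng.integers(0, 20, size=n_cols)]
        gaps = rng.random(n_cols) < gap_frac
        rows[f"t{t}"] = "".join(
            "-" if g else ch for ch, g in zip(chars, gaps)
        )
    return rows


# --- exact one-way ANOVA / Tukey-Kramer via direct formulas ----------------

def anova_f_exact(groups: list[list[float]]) -> tuple[Fraction, int, int]:
    """F statistic as an exact rational, plus degrees of freedom."""
    groups = [[Fraction(v) for v in g] for g in groups]
    k = len(groups)
    n_total = sum(len(g) for g in groups)
    grand = sum(sum(g) for g in groups) / n_total
    ss_between = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ss_within = sum(
        sum((v - sum(g) / len(g)) ** 2 for v in g) for g in groups
    )
    df_b, df_w = k - 1, n_total - k
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    return ms_b / ms_w, df_b, df_w


def tukey_kramer_q(groups: list[list[float]], i: int, j: int) -> float:
    """Observed studentized-range statistic for one group pair."""
    k = len(groups)
    n_total = sum(len(g) for g in groups)
    means = [sum(g) / len(g) for g in groups]
    ss_within = sum(
        sum((v - sum(g) / len(g)) ** 2 for v in g) for g in groups
    )
    ms_w = ss_within / (n_total - k)
    se = (ms_w / 2 * (1 / len(groups[i]) + 1 / len(groups[j]))) ** 0.5
    return abs(means[i] - means[j]) / se


# --- exhaustive unrooted topology enumeration + least squares --------------

def enumerate_topologies(n: int):
    """All (2n-5)!! fully resolved unrooted topologies over leaves 0..n-1.

    Yields adjacency maps {node: set(neighbors)}; leaves are 0..n-1 and
    internal nodes are >= n.
    """
    assert n >= 3
    base = {0: {n}, 1: {n}, 2: {n}, n: {0, 1, 2}}
    trees = [base]
    next_internal = n + 1
    for leaf in range(3, n):
        grown = []
        for adj in trees:
            edges = {
                tuple(sorted((u, v))) for u in adj for v in adj[u]
            }
            for u, v in sorted(edges):
                new = {node: set(nbrs) for node, nbrs in adj.items()}
                w = next_internal
                new[u].discard(v)
                new[v].discard(u)
                new[u].add(w)
                new[v].add(w)
                new[w] = {u, v, leaf}
                new[leaf] = {w}
                grown.append(new)
        trees = grown
        next_internal += 1
    return trees


def _paths_design(adj: dict[int, set[int]], n_leaves: int) -> np.ndarray:
    """Pairs-by-edges incidence matrix of leaf-to-leaf paths."""
    edges = sorted({tuple(sorted((u, v))) for u in adj for v in adj[u]})
    edge_idx = {e: i for i, e in enumerate(edges)}
    pairs = list(itertools.combinations(range(n_leaves), 2))
    design = np.zeros((len(pairs), len(edges)))
    for row, (a, b) in enumerate(pairs):
        # BFS path from a to b
        prev = {a: None}
        queue = [a]
        while queue:
            node = queue.pop(0)
            if node == b:
                break
            for nbr in adj[node]:
                if nbr not in prev:
                    prev[nbr] = node
                    queue.append(nbr)
        node = b
        while prev[node] is not None:
            design[row, edge_idx[tuple(sorted((node, prev[node])))]] = 1.0
            node = prev[node]
    return design


def least_squares_topology(matrix: np.ndarray):
    """Best unrooted topology by exhaustive ordinary-least-squares fit.

    Returns (adjacency, ssq).  Intended for n <= 6 (105 topologies).
    """
    n = matrix.shape[0]
    target = np.array(
        [matrix[i, j] for i, j in itertools.combinations(range(n), 2)]
    )
    best = None
    best_ssq = np.inf
    for adj in enumerate_topologies(n):
        design = _paths_design(adj, n)
        coef, _, _, _ = np.linalg.lstsq(design, target, rcond=None)
        ssq = float(((design @ coef - target) ** 2).sum())
        if ssq < best_ssq - 1e-15:
            best_ssq = ssq
            best = adj
    return best, best_ssq


def adjacency_bipartitions(adj: dict[int, set[int]], n_leaves: int) -> set[frozenset]:
    """Internal bipartitions of a plain adjacency map, canonicalized to the
    side not containing leaf 0."""
    out = set()
    edges = {tuple(sorted((u, v))) for u in adj for v in adj[u]}
    all_leaves = set(range(n_leaves))
    for u, v in edges:
        # leaves on v's side when (u, v) removed
        seen = {u, v}
        stack = [v]
        side = set()
        while stack:
            node = stack.pop()
            if node < n_leaves:
                side.add(node)
            for nbr in adj[node]:
                if nbr not in seen:
                    seen.add(nbr)
                    stack.append(nbr)
        if 2 <= len(side) <= n_leaves - 2:
            if 0 in side:
                side = all_leaves - side
            out.add(frozenset(side))
    return out


def random_additive_tree(rng: np.random.Generator, n: int):
    """Random resolved unrooted topology with positive branch lengths.

    Returns (adjacency, lengths) where lengths maps sorted edge -> length.
    """
    topologies = None
    # build by random sequential insertion instead of enumerating
    adj = {0: {n}, 1: {n}, 2: {n}, n: {0, 1, 2}}
    next_internal = n + 1
    for leaf in range(3, n):
        edges = sorted({tuple(sorted((u, v))) for u in adj for v in adj[u]})
        u, v = edges[rng.integers(0, len(edges))]
        w = next_internal
        next_internal += 1
        adj[u].discard(v)
        adj[v].discard(u)
        adj[u].add(w)
        adj[v].add(w)
        adj[w] = {u, v, leaf}
        adj[leaf] = {w}
    lengths = {
        tuple(sorted((u, v))): float(rng.uniform(0.05, 1.0))
        for u in adj
        for v in adj[u]
        if u < v
    }
    del topologies
    return adj, lengths


def additive_matrix_from(adj, lengths, n_leaves: int) -> np.ndarray:
    design = _paths_design(adj, n_leaves)
    edges = sorted({tuple(sorted((u, v))) for u in adj for v in adj[u]})
    vec = np.array([lengths[e] for e in edges])
    dists = design @ vec
    out = np.zeros((n_leaves, n_leaves))
    for (i, j), d in zip(itertools.combinations(range(n_leaves), 2), dists):
        out[i, j] = out[j, i] = d
    return out


# --- naive motif scan ------------------------------------------------------

def naive_iq_scan(seq: str) -> list[tuple[int, int, str]]:
    """Greedy left-to-right sliding-window scan with per-position character
    checks (no regex)."""

    def full_at(p: int) -> bool:
        if p + 11 > len(seq):
            return False
        s = seq[p : p + 11]
        return (
            s[0] in "FILV"
            and s[1] == "Q"
            and s[5] in "RK"
            and s[6] == "G"
            and s[10] in "RK"
        )

    def like_at(p: int) -> bool:
        if p + 10 > len(seq):
            return False
        s = seq[p : p + 10]
        return s[0] in "FILVM" and s[1] == "Q" and s[5] in "RK"

    hits = []
    pos = 0
    while pos < len(seq):
        if full_at(pos):
            hits.append((pos, pos + 11, "IQ_full"))
            pos += 11
        elif like_at(pos):
            hits.append((pos, pos + 10, "IQ_like"))
            pos += 10
        else:
            pos += 1
    return hits


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(AA[c] for c in rng.integers(0, 20, size=length))
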