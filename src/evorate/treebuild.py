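"""Distance trees: neighbor-joining with bootstrap support.

Trees are reconstructed from the pairwise distance matrix by Saitou-Nei
neighbor-joining (NJ): iteratively join the pair minimizing the Q-criterion

    Q(i,j) = (n - 2) d(i,j) - sum_k d(i,k) - sum_k d(j,k)

with the standard branch-length formulas.  NJ is consistent on additive
matrices (it returns the generating topology and reproduces all path
lengths exactly).  Support values come from the nonparametric bootstrap:
alignment columns are resampled with replacement, the matrix and NJ tree
recomputed, and each internal bipartition of the point-estimate tree is
scored by the percentage of replicates containing it.

Ties in the Q-criterion are broken by the smallest (i, j) index pair in the
current node ordering, so results are deterministic given input order.
Negative NJ branch lengths are clamped to zero with the deficit moved to
the sister branch, preserving the joined pair's path length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .distance import DistanceMatrix, distance_matrix_from_array, encode_alignment
from .errors import BootstrapFailureError, EvorateError, IncomparablePairError
from .seqio import ConcatenatedAlignment, LocusAlignment

Bipartition = frozenset  # frozenset of taxon names (side not holding the ref taxon)


@dataclass
class UnrootedTree:
    """Unrooted tree as an adjacency map with branch lengths.

    Nodes are integer ids; leaves ``0..n-1`` carry taxon labels.  A fully
    resolved unrooted tree over n taxa has exactly ``2n - 3`` branches.
    ``support`` maps internal bipartitions (canonicalized as the leaf set on
    the side *not* containing the first taxon) to bootstrap percentages.
    """

    taxa: list[str]
    adjacency: dict[int, list[tuple[int, float]]]
    support: dict[Bipartition, float] = field(default_factory=dict)

    @property
    def n_branches(self) -> int:
        return sum(len(v) for v in self.adjacency.values()) // 2

    def _edges(self) -> list[tuple[int, int, float]]:
        out = []
        for u, nbrs in self.adjacency.items():
            for v, length in nbrs:
                if u < v:
                    out.append((u, v, length))
        return out

    def _leaves_on_side(self, u: int, v: int) -> set[str]:
        """Leaf labels reachable from v when the edge (u, v) is removed."""
        seen = {u, v}
        stack = [v]
        labels = set()
        while stack:
            node = stack.pop()
            if node < len(self.taxa):
                labels.add(self.taxa[node])
            for nbr, _ in self.adjacency[node]:
                if nbr not in seen:
                    seen.add(nbr)
                    stack.append(nbr)
        return labels

    def canonical(self, side: set[str]) -> Bipartition:
        ref = self.taxa[0]
        if ref in side:
            side = set(self.taxa) - side
        return frozenset(side)

    def bipartitions(self) -> set[Bipartition]:
        """Internal (non-trivial) bipartitions: both sides hold >= 2 taxa."""
        n = len(self.taxa)
        out = set()
        for u, v, _ in self._edges():
            side = self._leaves_on_side(u, v)
            if 2 <= len(side) <= n - 2:
                out.add(self.canonical(side))
        return out

    def path_lengths(self) -> np.ndarray:
        """Matrix of leaf-to-leaf path lengths in input taxon order."""
        n = len(self.taxa)
        out = np.zeros((n, n))
        for leaf in range(n):
            dist = {leaf: 0.0}
            stack = [leaf]
            while stack:
                node = stack.pop()
                for nbr, length in self.adjacency[node]:
                    if nbr not in dist:
                        dist[nbr] = dist[node] + length
                        stack.append(nbr)
            for other in range(n):
                out[leaf, other] = dist[other]
        return out

    def newick(self, with_support: bool = False) -> str:
        """Newick string rooted at the central join (basal multifurcation)."""
        root = max(self.adjacency)  # last-created internal node

        def render(node: int, parent: int) -> str:
            children = [
                (nbr, length) for nbr, length in self.adjacency[node] if nbr != parent
            ]
            if not children:
                return self.taxa[node]
            parts = []
            for child, length in children:
                label = ""
                if with_support and child >= len(self.taxa):
                    side = self._leaves_on_side(node, child)
                    key = self.canonical(side)
                    if key in self.support:
                        label = f"{self.support[key]:g}"
                parts.append(f"{render(child, node)}{label}:{length:.10g}")
            return "(" + ",".join(parts) + ")"

        return render(root, -1) + ";"


def nj_tree(matrix: DistanceMatrix) -> UnrootedTree:
    """Saitou-Nei neighbor-joining tree from a complete distance matrix."""
    matrix.require_complete()
    n = matrix.n_taxa
    if n < 3:
        raise EvorateError("neighbor-joining needs at least 3 taxa")
    taxa = list(matrix.taxa)
    d = matrix.values.astype(float).copy()
    active = list(range(n))  # node ids, in creation order
    adjacency: dict[int, list[tuple[int, float]]] = {i: [] for i in range(n)}
    next_id = n
    # index into `d` for each active node
    pos = {node: idx for idx, node in enumerate(active)}

    def connect(u: int, v: int, length: float) -> None:
        adjacency[u].append((v, length))
        adjacency[v].append((u, length))

    while len(active) > 3:
        m = len(active)
        idx = [pos[node] for node in active]
        sub = d[np.ix_(idx, idx)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # deterministic tie-break: smallest (i, j) in current ordering
        best = np.unravel_index(np.argmin(q), q.shape)
        i, j = (best[0], best[1]) if best[0] < best[1] else (best[1], best[0])

        dij = sub[i, j]
        vi = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        vj = dij - vi
        if vi < 0.0:
            vj += vi
            vi = 0.0
        if vj < 0.0:
            vi += vj
            vj = 0.0

        new = next_id
        next_id += 1
        node_i, node_j = active[i], active[j]
        adjacency[new] = []
        connect(new, node_i, vi)
        connect(new, node_j, vj)

        # distances from the new node to every other active node
        others = [k for k in range(m) if k not in (i, j)]
        new_d = 0.5 * (sub[i, others] + sub[j, others] - dij)
        # reuse node_i's matrix slot for the new node
        pi = pos[node_i]
        for val, k in zip(new_d, others):
            pk = pos[active[k]]
            d[pi, pk] = d[pk, pi] = val
        pos[new] = pi
        del pos[node_i], pos[node_j]
        active = [node for node in active if node not in (node_i, node_j)]
        active.append(new)

    # final three-way join: closed-form central branch lengths
    a, b, c = active
    pa, pb, pc = pos[a], pos[b], pos[c]
    dab, dac, dbc = d[pa, pb], d[pa, pc], d[pb, pc]
    va = max(0.0, 0.5 * (dab + dac - dbc))
    vb = max(0.0, 0.5 * (dab + dbc - dac))
    vc = max(0.0, 0.5 * (dac + dbc - dab))
    center = next_id
    adjacency[center] = []
    connect(center, a, va)
    connect(center, b, vb)
    connect(center, c, vc)
    return UnrootedTree(taxa=taxa, adjacency=adjacency)


def bootstrap_support(
    aln: ConcatenatedAlignment | LocusAlignment,
    model: str = "p_distance",
    deletion: str = "pairwise",
    b_replicates: int = 500,
    seed: int = 0,
    stratified: bool = False,
) -> UnrootedTree:
    """NJ point-estimate tree with bootstrap bipartition support.

    Each replicate resamples alignment columns with replacement (same total
    length; with ``stratified=True`` columns are resampled within each locus
    partition), recomputes the distance matrix and the NJ tree.  Support of
    each internal bipartition of the point tree = percentage of successful
    replicates containing it.  Replicates producing an incomparable pair are
    dropped and counted; more than 10% dropped raises
    :class:`BootstrapFailureError`.  Replicate r draws from its own stream
    derived from (seed, r), so individual replicates are reproducible.
    """
    if b_replicates < 1:
        raise ValueError("need at least 1 bootstrap replicate")
    taxa, mat = encode_alignment(aln)
    point = nj_tree(distance_matrix_from_array(mat, taxa, model, deletion))
    target = point.bipartitions()
    counts = {bp: 0 for bp in target}

    n_cols = mat.shape[1]
    if stratified and isinstance(aln, ConcatenatedAlignment):
        blocks = [(start, end) for _, start, end in aln.partitions]
    else:
        blocks = [(0, n_cols)]

    n_dropped = 0
    n_ok = 0
    for r in range(b_replicates):
        rng = np.random.default_rng([seed, r])
        cols = np.concatenate(
            [rng.integers(start, end, size=end - start) for start, end in blocks]
        )
        try:
            dm = distance_matrix_from_array(mat[:, cols], taxa, model, deletion)
            dm.require_complete()
            rep = nj_tree(dm)
        except EvorateError:
            n_dropped += 1
            continue
        n_ok += 1
        for bp in rep.bipartitions():
            if bp in counts:
                counts[bp] += 1
    if n_dropped > 0.1 * b_replicates:
        raise BootstrapFailureError(
            f"{n_dropped}/{b_replicates} bootstrap replicates failed"
        )
    if n_ok:
        point.support = {bp: 100.0 * c / n_ok for bp, c in counts.items()}
    return point


@dataclass
class BipartitionComparison:
    shared: int
    unique_a: int
    unique_b: int

    @property
    def rf_distance(self) -> int:
        """Robinson-Foulds distance = total count of unshared bipartitions."""
        return self.unique_a + self.unique_b


def compare_bipartitions(
    tree_a: UnrootedTree, tree_b: UnrootedTree
) -> BipartitionComparison:
    """Shared/unique internal bipartition counts (Robinson-Foulds style)."""
    if set(tree_a.taxa) != set(tree_b.taxa):
        raise EvorateError("trees have different leaf sets")
    # re-canonicalize tree_b's bipartitions against tree_a's reference taxon
    ref = tree_a.taxa[0]
    all_taxa = set(tree_a.taxa)
    bps_a = tree_a.bipartitions()
    bps_b = {
        frozenset(all_taxa - bp) if ref in bp else bp for bp in tree_b.bipartitions()
    }
    shared = bps_a & bps_b
    return BipartitionComparison(
        shared=len(shared),
        unique_a=len(bps_a - shared),
        unique_b=len(bps_b - shared),
    )


def additive_matrix(tree: UnrootedTree) -> DistanceMatrix:
    """Exact path-length (additive) matrix of a tree — handy for testing."""
    values = tree.path_lengths()
    return DistanceMatrix(
        taxa=list(tree.taxa),
        values=values,
        model="p_distance",
        deletion="pairwise",
        sites_used=np.zeros_like(values, dtype=int),
    )


__all__ = [
    "UnrootedTree",
    "nj_tree",
    "bootstrap_support",
    "compare_bipartitions",
    "BipartitionComparison",
    "additive_matrix",
]
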