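"""NeighbourNet: circular split systems from distance matrices.

The construction runs in two stages:

1. **Agglomeration.**  A neighbour-joining-style selection repeatedly
   picks a pair of clusters (then a pair of nodes, one from each) to
   join.  Joined nodes form paths; any path longer than two nodes is
   reduced to two fresh nodes whose distances to the rest are fixed
   linear combinations of the replaced triple.  Unwinding the reductions
   yields a circular ordering of the taxa.  Tree metrics — and circular
   split metrics in general — are recovered consistently.

2. **Weight estimation.**  For the found ordering, all ``n(n-1)/2``
   interval splits (one side a contiguous arc of the circle) are given
   non-negative weights by a constrained least-squares fit of split
   distances to the input matrix (active-set NNLS).  Splits whose weight
   falls at or below ``weight_threshold`` are dropped.

Ties in the selection criteria are broken by the lexicographically
smallest index pair, so the construction is deterministic without seeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls as _scipy_nnls

from .core import DistanceMatrix, Split, TaxonSet, WeightedSplitSystem

__all__ = [
    "CircularOrdering",
    "circular_interval_splits",
    "nnls_split_weights",
    "neighbor_net",
]


@dataclass(frozen=True)
class CircularOrdering:
    """A permutation of taxon indices laid out around a circle.

    Every split of a circular system is an interval of this ordering:
    one side is a contiguous arc, the other its complement.
    """

    ordering: tuple[int, ...]

    def __post_init__(self) -> None:
        n = len(self.ordering)
        if sorted(self.ordering) != list(range(n)):
            raise ValueError("ordering must be a permutation of 0..n-1")

    @property
    def n(self) -> int:
        return len(self.ordering)

    def canonical(self) -> "CircularOrdering":
        """Rotate so taxon 0 leads; orient so the smaller neighbour follows.

        Rotations and reflections of a circular ordering describe the
        same split system; this fixes one representative.
        """
        order = list(self.ordering)
        i0 = order.index(0)
        order = order[i0:] + order[:i0]
        if len(order) > 2 and order[-1] < order[1]:
            order = [order[0]] + order[:0:-1]
        return CircularOrdering(tuple(order))


def circular_interval_splits(ordering: CircularOrdering) -> list[Split]:
    """All ``n(n-1)/2`` interval splits of a circular ordering.

    Enumerated as arcs over positions ``1..n-1`` (never containing the
    taxon at position 0), so each split appears exactly once.
    """
    order = ordering.ordering
    n = len(order)
    out: list[Split] = []
    for p in range(1, n):
        for q in range(p, n):
            out.append(Split.of(frozenset(order[p : q + 1]), n))
    return out


def nnls_split_weights(
    ordering: CircularOrdering, D: DistanceMatrix
) -> np.ndarray:
    """Non-negative least-squares weights for all interval splits.

    Minimizes ``sum_{i<j} (D_ij - sum_S w_S [S separates i,j])^2``
    subject to ``w >= 0``, via the active-set NNLS algorithm.  The
    returned vector is aligned with :func:`circular_interval_splits`.
    Deterministic for a fixed ordering.
    """
    n = D.n
    if ordering.n != n:
        raise ValueError(
            f"ordering over {ordering.n} taxa does not match matrix of {n}"
        )
    splits = circular_interval_splits(ordering)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    a = np.zeros((len(pairs), len(splits)))
    for col, sp in enumerate(splits):
        for row, (i, j) in enumerate(pairs):
            if sp.separates(i, j):
                a[row, col] = 1.0
    b = np.array([D.values[i, j] for i, j in pairs])
    w, _ = _scipy_nnls(a, b)
    return w


# ---------------------------------------------------------------------------
# Stage 1: agglomerative circular ordering
# ---------------------------------------------------------------------------

def _nn_cycle(dist: np.ndarray) -> list[int]:
    """The NeighbourNet circular ordering of ``0..n-1`` for matrix ``dist``."""
    n = dist.shape[0]
    if n <= 3:
        return list(range(n))

    # node distance store, grown as reductions create new nodes
    cap = 3 * n + 6
    d = np.zeros((cap, cap))
    d[:n, :n] = dist
    next_id = n

    clusters: list[list[int]] = [[i] for i in range(n)]
    reductions: list[tuple[int, int, int, int, int]] = []  # (u, v, a, b, c)

    def cluster_dist(c1: list[int], c2: list[int]) -> float:
        return float(np.mean([d[x, y] for x in c1 for y in c2]))

    while sum(len(c) for c in clusters) > 3:
        m = len(clusters)

        # --- select the pair of clusters ---
        if m == 2:
            bi, bj = 0, 1
        else:
            cd = np.zeros((m, m))
            for i in range(m):
                for j in range(i + 1, m):
                    cd[i, j] = cd[j, i] = cluster_dist(clusters[i], clusters[j])
            r = cd.sum(axis=1)
            best = None
            bi = bj = -1
            for i in range(m):
                for j in range(i + 1, m):
                    q = (m - 2) * cd[i, j] - r[i] - r[j]
                    if best is None or q < best - 1e-14:
                        best, bi, bj = q, i, j

        ci, cj = clusters[bi], clusters[bj]

        # --- select the node pair: members of the two chosen clusters are
        # treated as separate units, every other cluster as one unit ---
        others = [clusters[k] for k in range(m) if k not in (bi, bj)]
        members = ci + cj
        m_hat = len(members) + len(others)

        def unit_sum(x: int) -> float:
            s = sum(d[x, z] for z in members if z != x)
            s += sum(cluster_dist([x], oc) for oc in others)
            return s

        best_q = None
        bx = by = -1
        for x in sorted(ci):
            rx = unit_sum(x)
            for y in sorted(cj):
                q = (m_hat - 2) * d[x, y] - rx - unit_sum(y)
                if best_q is None or q < best_q - 1e-14:
                    best_q, bx, by = q, x, y

        # --- merge into one path: ci oriented to end at bx, cj to start at by
        left = ci if ci[-1] == bx else ci[::-1]
        right = cj if cj[0] == by else cj[::-1]
        path = left + right

        # --- reduce until the path has two nodes again ---
        while len(path) > 2:
            a_, b_, c_ = path[0], path[1], path[2]
            u, v = next_id, next_id + 1
            next_id += 2
            active = [z for c in clusters for z in c if z not in (a_, b_, c_)]
            active += path[3:]
            for z in set(active):
                d[u, z] = d[z, u] = (2.0 * d[a_, z] + d[b_, z]) / 3.0
                d[v, z] = d[z, v] = (d[b_, z] + 2.0 * d[c_, z]) / 3.0
            d[u, v] = d[v, u] = (d[a_, b_] + d[a_, c_] + d[b_, c_]) / 3.0
            reductions.append((u, v, a_, b_, c_))
            path = [u, v] + path[3:]

        pos = min(bi, bj)
        clusters = [c for k, c in enumerate(clusters) if k not in (bi, bj)]
        clusters.insert(pos, path)

    # --- stitch the remaining paths (<= 3 nodes total) into a cycle ---
    cycle: list[int] = [z for c in clusters for z in c]

    # --- unwind the reductions ---
    for u, v, a_, b_, c_ in reversed(reductions):
        k = len(cycle)
        iu = cycle.index(u)
        if cycle[(iu + 1) % k] == v:
            rot = cycle[iu:] + cycle[:iu]       # [u, v, rest...]
            cycle = [a_, b_, c_] + rot[2:]
        elif cycle[(iu - 1) % k] == v:
            iv = (iu - 1) % k
            rot = cycle[iv:] + cycle[:iv]       # [v, u, rest...]
            cycle = [c_, b_, a_] + rot[2:]
        else:
            raise AssertionError("reduction pair not adjacent during expansion")

    return cycle


def neighbor_net(
    D: DistanceMatrix, weight_threshold: float = 1e-6
) -> tuple[WeightedSplitSystem, CircularOrdering]:
    """Build a circular weighted split system fitting a distance matrix.

    Stage 1 finds a circular ordering by agglomerative neighbour
    selection; stage 2 assigns non-negative least-squares weights to all
    interval splits of that ordering and drops those at or below
    ``weight_threshold`` (default 1e-6 in input-distance units, matching
    the convention of discarding numerically-zero splits).

    Returns the split system (trivial/pendant splits included whenever
    their fitted weight is positive) and the canonical circular ordering.
    On additive tree metrics the tree's splits and branch lengths are
    recovered exactly; on general matrices the system's split distances
    are the best non-negative circular approximation for the ordering
    found.
    """
    if weight_threshold < 0:
        raise ValueError("weight_threshold must be >= 0")
    n = D.n
    if n < 2:
        raise ValueError("need at least 2 taxa")
    taxa = TaxonSet(D.labels)
    if n == 2:
        ordering = CircularOrdering((0, 1))
        w = float(D.values[0, 1])
        splits = [(Split.of({0}, 2), w)] if w > weight_threshold else []
        return WeightedSplitSystem(taxa, splits), ordering

    ordering = CircularOrdering(tuple(_nn_cycle(D.values))).canonical()
    weights = nnls_split_weights(ordering, D)
    splits = circular_interval_splits(ordering)
    kept = [
        (sp, float(w))
        for sp, w in zip(splits, weights)
        if w > weight_threshold
    ]
    return WeightedSplitSystem(taxa, kept), ordering
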