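"""Core domain types for split-network diversity analysis.

A *split* is a bipartition of the taxon set — the network analogue of a
tree edge.  A weighted collection of splits (a *split system*) carries all
the information the prioritization indices need: the phylogenetic
diversity of any taxon subset is the total weight of splits with members
of the subset on both sides, and on trees this reduces to spanning
subtree length.

This module provides the taxon set, split, weighted split system,
extinction profile and ranking-table containers, conversion of newick
trees (via dendropy) into split systems, and split-distance evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import dendropy
import numpy as np

__all__ = [
    "TaxonSet",
    "Split",
    "WeightedSplitSystem",
    "ExtinctionProfile",
    "DistanceMatrix",
    "RankingRow",
    "RankingTable",
    "splits_from_tree",
]


class TaxonSet:
    """An ordered collection of unique, non-empty taxon labels.

    The order fixes the 0-based integer indexing used by :class:`Split`;
    external formats (e.g. NEXUS) keep their own 1-based conventions.
    """

    __slots__ = ("labels", "_index")

    def __init__(self, labels: Iterable[str]):
        labels = tuple(str(x) for x in labels)
        if any(not lab for lab in labels):
            raise ValueError("taxon labels must be non-empty strings")
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise ValueError(f"duplicate taxon labels: {dupes}")
        self.labels = labels
        self._index = {lab: i for i, lab in enumerate(labels)}

    @property
    def n(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise KeyError(f"unknown taxon label: {label!r}") from None

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self) -> Iterator[str]:
        return iter(self.labels)

    def __contains__(self, label: object) -> bool:
        return label in self._index

    def __eq__(self, other: object) -> bool:
        return isinstance(other, TaxonSet) and self.labels == other.labels

    def __hash__(self) -> int:
        return hash(self.labels)

    def __repr__(self) -> str:
        return f"TaxonSet({list(self.labels)!r})"


@dataclass(frozen=True)
class Split:
    """A bipartition (A, B) of the taxon indices ``0..n-1``.

    Canonical orientation: ``side_a`` contains taxon index 0, so equality
    is independent of the orientation the split was constructed with.
    """

    side_a: frozenset[int]
    side_b: frozenset[int]

    def __init__(self, side_a: Iterable[int], side_b: Iterable[int]):
        a, b = frozenset(side_a), frozenset(side_b)
        if not a or not b:
            raise ValueError("both sides of a split must be non-empty")
        if a & b:
            raise ValueError(f"split sides overlap: {sorted(a & b)}")
        if min(b) < min(a):
            a, b = b, a
        object.__setattr__(self, "side_a", a)
        object.__setattr__(self, "side_b", b)

    @classmethod
    def of(cls, side: Iterable[int], n: int) -> "Split":
        """Build a split from one side and the total taxon count."""
        side = frozenset(side)
        if not side <= set(range(n)):
            raise ValueError("side contains indices outside 0..n-1")
        return cls(side, frozenset(range(n)) - side)

    @property
    def n(self) -> int:
        return len(self.side_a) + len(self.side_b)

    def separates(self, i: int, j: int) -> bool:
        return (i in self.side_a) != (j in self.side_a)

    def side_of(self, i: int) -> frozenset[int]:
        if i in self.side_a:
            return self.side_a
        if i in self.side_b:
            return self.side_b
        raise KeyError(f"taxon index {i} not in split")

    def other_side(self, i: int) -> frozenset[int]:
        if i in self.side_a:
            return self.side_b
        if i in self.side_b:
            return self.side_a
        raise KeyError(f"taxon index {i} not in split")

    def is_trivial(self) -> bool:
        """Pendant split: one side is a single taxon."""
        return len(self.side_a) == 1 or len(self.side_b) == 1

    def __repr__(self) -> str:
        return f"Split({sorted(self.side_a)}|{sorted(self.side_b)})"


class WeightedSplitSystem:
    """A taxon set plus weighted splits; the object all indices run on.

    Weights are non-negative and in the units of the input distances.
    Duplicate splits are rejected; zero-weight splits are allowed (they
    never affect any index but keep the representation lossless).
    """

    def __init__(self, taxa: TaxonSet, splits: Iterable[tuple[Split, float]]):
        self.taxa = taxa
        items: list[tuple[Split, float]] = []
        seen: set[Split] = set()
        for sp, w in splits:
            if sp.n != taxa.n:
                raise ValueError(
                    f"split over {sp.n} taxa in a system of {taxa.n}"
                )
            w = float(w)
            if not np.isfinite(w) or w < 0:
                raise ValueError(f"split weight must be finite and >= 0, got {w}")
            if sp in seen:
                raise ValueError(f"duplicate split: {sp}")
            seen.add(sp)
            items.append((sp, w))
        self._splits = tuple(items)

    @property
    def splits(self) -> tuple[tuple[Split, float], ...]:
        return self._splits

    @property
    def n(self) -> int:
        return self.taxa.n

    def total_diversity(self) -> float:
        """Sum of all split weights: the diversity of the full taxon set."""
        return float(sum(w for _, w in self._splits))

    def split_distance(self, i: str, j: str) -> float:
        """Total weight of splits separating taxa ``i`` and ``j``.

        Generalizes patristic distance; symmetric and zero on the diagonal.
        """
        ii, jj = self.taxa.index(i), self.taxa.index(j)
        if ii == jj:
            return 0.0
        return float(
            sum(w for sp, w in self._splits if sp.separates(ii, jj))
        )

    def distance_matrix(self) -> "DistanceMatrix":
        n = self.n
        d = np.zeros((n, n))
        for sp, w in self._splits:
            a = np.fromiter(sp.side_a, dtype=int)
            b = np.fromiter(sp.side_b, dtype=int)
            d[np.ix_(a, b)] += w
        d = d + d.T
        return DistanceMatrix(list(self.taxa), d)

    def __len__(self) -> int:
        return len(self._splits)

    def __repr__(self) -> str:
        return (
            f"WeightedSplitSystem(n={self.n}, splits={len(self._splits)}, "
            f"total={self.total_diversity():g})"
        )


def total_diversity(system: WeightedSplitSystem) -> float:
    return system.total_diversity()


def split_distance(system: WeightedSplitSystem, i: str, j: str) -> float:
    return system.split_distance(i, j)


class ExtinctionProfile:
    """Per-taxon extinction probability epsilon in [0, 1].

    ``pext[t]`` is the probability that taxon ``t`` goes extinct over the
    planning horizon (e.g. the next 100 years); extinction events are
    treated as independent across taxa.
    """

    def __init__(self, pext: Mapping[str, float]):
        clean: dict[str, float] = {}
        for lab, eps in pext.items():
            eps = float(eps)
            if not 0.0 <= eps <= 1.0:
                raise ValueError(
                    f"extinction probability for {lab!r} outside [0, 1]: {eps}"
                )
            clean[str(lab)] = eps
        self._pext = clean

    def __getitem__(self, label: str) -> float:
        try:
            return self._pext[label]
        except KeyError:
            raise KeyError(f"no extinction probability for taxon {label!r}") from None

    def __contains__(self, label: object) -> bool:
        return label in self._pext

    def items(self):
        return self._pext.items()

    def validate_for(self, taxa: TaxonSet) -> None:
        missing = [t for t in taxa if t not in self._pext]
        if missing:
            raise KeyError(f"extinction profile missing taxa: {missing}")

    def with_pext(self, label: str, eps: float) -> "ExtinctionProfile":
        """A copy with one taxon's probability replaced."""
        if label not in self._pext:
            raise KeyError(f"no extinction probability for taxon {label!r}")
        d = dict(self._pext)
        d[label] = eps
        return ExtinctionProfile(d)

    def as_array(self, taxa: TaxonSet) -> np.ndarray:
        self.validate_for(taxa)
        return np.array([self._pext[t] for t in taxa], dtype=float)

    def __repr__(self) -> str:
        return f"ExtinctionProfile({self._pext!r})"


class DistanceMatrix:
    """Symmetric non-negative dissimilarities with zero diagonal."""

    def __init__(self, labels: Sequence[str], values: np.ndarray, *, tol: float = 1e-8):
        self.labels = tuple(str(x) for x in labels)
        v = np.asarray(values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} labels")
        if np.isnan(v).any():
            raise ValueError("distance matrix contains NaN entries")
        if not np.allclose(v, v.T, atol=tol, rtol=0):
            raise ValueError("distance matrix is not symmetric")
        if np.abs(np.diag(v)).max(initial=0.0) > tol:
            raise ValueError("distance matrix diagonal is not zero")
        if v.min(initial=0.0) < -tol:
            raise ValueError("distance matrix has negative entries")
        v = np.clip((v + v.T) / 2.0, 0.0, None)
        np.fill_diagonal(v, 0.0)
        self.values = v

    @property
    def n(self) -> int:
        return len(self.labels)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    def __repr__(self) -> str:
        return f"DistanceMatrix(n={self.n})"


@dataclass
class RankingRow:
    label: str
    values: dict[str, float]
    rank: int
    iteration_picked: int | None = None
    tied: bool = False


@dataclass
class RankingTable:
    """Per-taxon index values and ordinal ranks (1 = highest priority).

    Exact ties are broken by lexicographic label order and flagged rather
    than hidden, so downstream users can bring other criteria to bear.
    For iterative rankings, ``iteration_trace[k]`` holds the full index
    vector computed at iteration ``k``.
    """

    rows: list[RankingRow]
    iteration_trace: list[dict[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.rows)
        if sorted(r.rank for r in self.rows) != list(range(1, n + 1)):
            raise ValueError("ranks must be a permutation of 1..n")

    def rank_of(self, label: str) -> int:
        for r in self.rows:
            if r.label == label:
                return r.rank
        raise KeyError(f"no row for taxon {label!r}")

    def by_rank(self) -> list[RankingRow]:
        return sorted(self.rows, key=lambda r: r.rank)

    def to_dataframe(self):
        import pandas as pd

        value_keys: list[str] = []
        for r in self.rows:
            for k in r.values:
                if k not in value_keys:
                    value_keys.append(k)
        recs = []
        for r in self.by_rank():
            rec = {"taxon": r.label}
            rec.update({k: r.values.get(k, np.nan) for k in value_keys})
            rec["rank"] = r.rank
            rec["iteration_picked"] = r.iteration_picked
            rec["tied"] = r.tied
            recs.append(rec)
        return pd.DataFrame.from_records(recs)


# ---------------------------------------------------------------------------
# Tree -> split system
# ---------------------------------------------------------------------------

def _as_dendropy_tree(tree: "str | dendropy.Tree") -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        return tree
    try:
        return dendropy.Tree.get(
            data=str(tree),
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as e:
        raise ValueError(f"duplicate leaf labels in newick input: {e}") from None


def splits_from_tree(tree: "str | dendropy.Tree") -> WeightedSplitSystem:
    """Convert a tree with branch lengths into its weighted split system.

    Split systems are unrooted objects, so a degree-2 root is suppressed:
    its two incident edges induce the same bipartition and their lengths
    are summed.  Each remaining edge contributes one split whose weight is
    the edge length (``None`` lengths count as 0; negative lengths are an
    error).  Trivial (pendant) splits are included.

    Parameters
    ----------
    tree:
        A newick string or a :class:`dendropy.Tree`.
    """
    t = _as_dendropy_tree(tree)
    leaves = [lf for lf in t.leaf_node_iter()]
    labels = [lf.taxon.label if lf.taxon is not None else None for lf in leaves]
    if any(lab is None for lab in labels):
        raise ValueError("tree has unlabelled leaves")
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise ValueError(f"duplicate leaf labels: {dupes}")
    if len(labels) < 2:
        raise ValueError("tree must have at least 2 leaves")

    taxa = TaxonSet(labels)
    acc: dict[Split, float] = {}
    for node in t.preorder_node_iter():
        if node.parent_node is None:
            continue  # the root edge carries no bipartition
        length = node.edge.length
        w = 0.0 if length is None else float(length)
        if w < 0:
            raise ValueError(f"negative branch length: {w}")
        below = frozenset(
            taxa.index(lf.taxon.label) for lf in node.leaf_iter()
        )
        if len(below) == taxa.n:
            # can happen only for a unifurcating root edge; no bipartition
            continue
        sp = Split.of(below, taxa.n)
        acc[sp] = acc.get(sp, 0.0) + w
    return WeightedSplitSystem(taxa, list(acc.items()))
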