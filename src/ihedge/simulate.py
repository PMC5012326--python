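"""Synthetic data generators, brute-force oracles, and reference fixtures.

Everything here exists so that every pipeline stage can be exercised
without external downloads:

* brute-force oracles for the Shapley index (all ``n!`` arrival orders)
  and expected phylogenetic diversity (all ``2^n`` survival outcomes),
  implemented without sharing code with the fast closed forms they check;
* seeded random trees, circular split systems, and population alignments
  with known structure;
* the published SH and I-HEDGE rank columns for the 12 Galapagos giant
  tortoise taxa, used as a desk-scale concordance fixture.

Size caps on the oracles (``n! `` and ``2^n``) keep full-enumeration
checks in the seconds-to-minutes range on a single CPU.
"""

from __future__ import annotations

import itertools
from typing import Sequence

import numpy as np
import pandas as pd

from .core import ExtinctionProfile, Split, TaxonSet, WeightedSplitSystem

__all__ = [
    "brute_force_shapley",
    "enumerate_expected_pd",
    "random_tree",
    "random_circular_system",
    "random_alignment",
    "random_profile",
    "galapagos_rankings",
]


# ---------------------------------------------------------------------------
# Brute-force oracles
# ---------------------------------------------------------------------------

def _subset_pd(split_sides: list[tuple[frozenset[int], frozenset[int], float]],
               subset: frozenset[int]) -> float:
    """PD of a taxon subset: weight of splits with members on both sides."""
    total = 0.0
    for a, b, w in split_sides:
        if (subset & a) and (subset & b):
            total += w
    return total


def brute_force_shapley(system: WeightedSplitSystem) -> dict[str, float]:
    """Shapley values by full enumeration of all ``n!`` arrival orders.

    For every permutation of the taxa, each taxon's marginal gain in
    subset PD upon arrival is recorded; the Shapley value is the average
    over permutations.  Exponential-time oracle, capped at n <= 8.
    """
    n = system.n
    if n > 8:
        raise ValueError("brute-force Shapley is capped at n <= 8")
    sides = [(sp.side_a, sp.side_b, w) for sp, w in system.splits]
    totals = np.zeros(n)
    count = 0
    for order in itertools.permutations(range(n)):
        present: frozenset[int] = frozenset()
        pd_prev = 0.0
        for idx in order:
            present = present | {idx}
            pd_now = _subset_pd(sides, present)
            totals[idx] += pd_now - pd_prev
            pd_prev = pd_now
        count += 1
    totals /= count
    return {system.taxa.labels[i]: float(totals[i]) for i in range(n)}


def enumerate_expected_pd(
    system: WeightedSplitSystem, eps: ExtinctionProfile
) -> float:
    """Expected PD by exhaustive enumeration of all ``2^n`` outcomes.

    Each survival outcome (a subset of surviving taxa) is weighted by its
    probability under independent extinctions; PD of the survivor set is
    summed.  Capped at n <= 15.
    """
    n = system.n
    if n > 15:
        raise ValueError("exhaustive expected PD is capped at n <= 15")
    e = eps.as_array(system.taxa)
    sides = [(sp.side_a, sp.side_b, w) for sp, w in system.splits]
    total = 0.0
    for bits in itertools.product((0, 1), repeat=n):
        prob = 1.0
        for i, alive in enumerate(bits):
            prob *= (1.0 - e[i]) if alive else e[i]
        if prob == 0.0:
            continue
        survivors = frozenset(i for i, alive in enumerate(bits) if alive)
        total += prob * _subset_pd(sides, survivors)
    return total


# ---------------------------------------------------------------------------
# Random fixtures
# ---------------------------------------------------------------------------

def _rng(seed: "int | np.random.Generator") -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def random_tree(n: int, seed: "int | np.random.Generator",
                mean_branch_length: float = 1.0) -> str:
    """A random binary tree on taxa ``t1..tn`` as a newick string.

    Topology by uniform sequential joining; branch lengths iid
    exponential with the given mean.
    """
    if n < 2:
        raise ValueError("need n >= 2 leaves")
    rng = _rng(seed)

    def bl() -> float:
        return float(rng.exponential(mean_branch_length))

    nodes = [f"t{i + 1}:{bl():.10f}" for i in range(n)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = f"({nodes[i]},{nodes[j]}):{bl():.10f}"
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)]
        nodes.append(merged)
    return f"({nodes[0]},{nodes[1]});"


def random_circular_system(
    n: int,
    seed: "int | np.random.Generator",
    n_splits: int | None = None,
    include_pendants: bool = True,
) -> tuple[WeightedSplitSystem, list[int]]:
    """A random circular split system and its underlying ordering.

    Splits are random arcs of a random circular ordering of ``t1..tn``
    with weights drawn from ``Exp(1) + 0.05`` (bounded away from zero so
    generate-and-refit comparisons are well-posed).  Returns
    ``(system, ordering)`` with the ordering as taxon indices.
    """
    if n < 2:
        raise ValueError("need n >= 2 taxa")
    rng = _rng(seed)
    taxa = TaxonSet([f"t{i + 1}" for i in range(n)])
    order = list(rng.permutation(n))

    # all candidate arcs [p..q] of positions 1..n-1 (never containing
    # position 0, so each interval split appears exactly once)
    arcs = [(p, q) for p in range(1, n) for q in range(p, n)]
    chosen: set[tuple[int, int]] = set()
    if include_pendants:
        chosen.update((p, p) for p in range(1, n))
        chosen.add((1, n - 1))  # pendant of the taxon at position 0
    k = n_splits if n_splits is not None else max(1, n)
    extra = [a for a in arcs if a not in chosen]
    take = min(k, len(extra))
    if take:
        idx = rng.choice(len(extra), size=take, replace=False)
        chosen.update(extra[i] for i in idx)

    splits = []
    for p, q in sorted(chosen):
        side = frozenset(order[p : q + 1])
        w = float(rng.exponential(1.0) + 0.05)
        splits.append((Split.of(side, n), w))
    return WeightedSplitSystem(taxa, splits), order


def random_profile(
    taxa: TaxonSet, seed: "int | np.random.Generator"
) -> ExtinctionProfile:
    """Uniform(0.05, 0.95) extinction probabilities for each taxon."""
    rng = _rng(seed)
    return ExtinctionProfile(
        {lab: float(rng.uniform(0.05, 0.95)) for lab in taxa}
    )


_BASES = np.array(list("ACGT"))
# transition partner of each base (A<->G, C<->T)
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


def _mutate(seq: np.ndarray, rate: float, ts_tv_ratio: float,
            rng: np.random.Generator) -> np.ndarray:
    """Per-site substitution with the given expected rate.

    Each site mutates independently with probability ``rate``; a mutation
    is a transition with odds ``ts_tv_ratio : 1`` against a random
    transversion.  Site-independent, no indels — deliberately simple, it
    feeds the distance and differentiation stages, not inference.
    """
    out = seq.copy()
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        base = out[i]
        if rng.random() < ts_tv_ratio / (ts_tv_ratio + 1.0):
            out[i] = _TRANSITION[base]
        else:
            tv = [b for b in "ACGT" if b != base and b != _TRANSITION[base]]
            out[i] = tv[rng.integers(len(tv))]
    return out


def random_alignment(
    pops: int,
    n_per_pop: int,
    length: int,
    divergence: float,
    seed: "int | np.random.Generator",
    within_rate: float = 0.005,
    ts_tv_ratio: float = 4.0,
) -> tuple[dict[str, list[str]], dict[str, str]]:
    """Seeded synthetic population alignment with controlled divergence.

    A random ancestral sequence is mutated independently into one
    ancestor per population at per-site rate ``divergence``; individuals
    then mutate from their population ancestor at ``within_rate``.
    Higher ``divergence`` relative to ``within_rate`` pushes pairwise
    population differentiation (Phi_ST) towards 1; ``divergence = 0``
    leaves no among-population structure.

    Returns ``(populations, popmap)`` where ``populations`` maps a
    population label to its list of sequences and ``popmap`` maps each
    sequence id ``pop<p>_ind<k>`` to its population label.
    """
    if pops < 1 or n_per_pop < 1 or length < 1:
        raise ValueError("pops, n_per_pop and length must all be >= 1")
    rng = _rng(seed)
    ancestor = _BASES[rng.integers(0, 4, size=length)]
    populations: dict[str, list[str]] = {}
    popmap: dict[str, str] = {}
    for p in range(1, pops + 1):
        pop_label = f"pop{p}"
        pop_anc = _mutate(ancestor, divergence, ts_tv_ratio, rng)
        seqs = []
        for k in range(1, n_per_pop + 1):
            ind = _mutate(pop_anc, within_rate, ts_tv_ratio, rng)
            seqs.append("".join(ind))
            popmap[f"{pop_label}_ind{k}"] = pop_label
        populations[pop_label] = seqs
    return populations, popmap


# ---------------------------------------------------------------------------
# Published reference rankings (Galapagos giant tortoises)
# ---------------------------------------------------------------------------

_GALAPAGOS_ROWS = [
    # island, species, N (sample size), SH rank, I-HEDGE rank
    ("Pinta", "abingdoni", 12, 4, 1),
    ("Floreana", "nigra", 20, 6, 2),
    ("Santa Cruz", "donfaustoi", 20, 1, 3),
    ("San Cristobal", "chathamensis", 19, 3, 4),
    ("Espanola", "hoodensis", 15, 2, 5),
    ("Pinzon", "ephippium", 27, 5, 6),
    ("Santa Cruz", "porteri", 23, 7, 7),
    ("Isabela", "microphyes", 21, 8, 8),
    ("Isabela", "vandenburghi", 28, 9, 9),
    ("Isabela", "becki", 45, 10, 10),
    ("Santiago", "darwini", 21, 11, 11),
    ("Isabela", "vicina", 116, 12, 12),
]


def galapagos_rankings() -> pd.DataFrame:
    """Published SH and I-HEDGE ranks for the 12 Galapagos tortoise taxa.

    The network-based prioritization of the giant tortoise radiation
    (mitochondrial control-region data; two recently extinct taxa,
    *abingdoni* and *nigra*, included with p(ext) = 1).  Columns:
    ``island, species, n_samples, sh_rank, ihedge_rank``; rows are in
    I-HEDGE order, so ``ihedge_rank`` is 1..12.
    """
    return pd.DataFrame(
        _GALAPAGOS_ROWS,
        columns=["island", "species", "n_samples", "sh_rank", "ihedge_rank"],
    )
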