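"""Prioritization indices on weighted split systems.

The diversity "game" behind all of these: a split S = (A, B) with weight
lambda_S contributes its weight to the phylogenetic diversity (PD) of a
taxon subset Y exactly when Y intersects both sides of S.  On trees this
is spanning subtree length; on networks it is split diversity.

Four per-taxon indices are provided:

* **SH** — the Shapley value of the split-diversity game: the average
  marginal PD contribution of a taxon over all arrival orders.  On trees
  it coincides with the fair-proportion / evolutionary-distinctiveness
  score.  For split systems there is a closed form,

  ``SH(i) = sum over splits S=(A,B), i in A of lambda_S * |B| / (|A| * n)``.

* **HED** — heightened evolutionary distinctiveness: the expected
  marginal PD contribution of taxon i given independent extinction
  probabilities ``eps_j`` of all other taxa,

  ``HED(i) = sum over S=(A,B), i in A of
  lambda_S * prod_{j in A, j != i} eps_j * (1 - prod_{k in B} eps_k)``.

  A taxon's own extinction probability does not enter its HED score.

* **HEDGE** — ``eps_i * HED(i)``: the gain in expected PD from making
  taxon i completely safe (``eps_i -> 0``).

* **I-HEDGE** — iterative HEDGE: repeatedly rank the top-HEDGE taxon,
  set its extinction probability to a small "saved" value (0.001 by
  default), and recompute.  The resulting ranked list accounts for
  complementarity: once a taxon is secured, the shared diversity it
  carries no longer inflates its neighbours' scores.
"""

from __future__ import annotations

import itertools
import math
from typing import Sequence

import numpy as np

from .core import (
    ExtinctionProfile,
    RankingRow,
    RankingTable,
    WeightedSplitSystem,
)

__all__ = [
    "IndexVector",
    "shapley",
    "expected_pd",
    "hed",
    "hedge",
    "i_hedge",
    "rank_values",
    "DEFAULT_IUCN_TABLE",
    "iucn_to_pext",
    "spearman_rank",
    "spearman_pvalue",
]

#: Exact-tie tolerance used when flagging tied index values.  Values are
#: compared after rounding to 12 significant digits so that analytically
#: identical scores computed along different float paths still register
#: as ties, while genuinely distinct scores essentially never do.
_TIE_REL_TOL = 1e-12


class IndexVector(dict):
    """Per-taxon index values; a dict ``label -> value`` tagged with the kind."""

    def __init__(self, values: dict[str, float], kind: str):
        super().__init__(values)
        self.kind = kind

    def as_series(self):
        import pandas as pd

        return pd.Series(dict(self), name=self.kind)

    def argmax(self) -> str:
        """Label with the highest value; exact ties broken lexicographically."""
        best = max(self.values())
        tied = sorted(k for k, v in self.items() if _tie_eq(v, best))
        return tied[0]


def _tie_eq(a: float, b: float) -> bool:
    return math.isclose(a, b, rel_tol=_TIE_REL_TOL, abs_tol=1e-300)


def shapley(system: WeightedSplitSystem) -> IndexVector:
    """Shapley index SH of every taxon.

    Uses the closed form ``SH(i) = sum_{S=(A,B): i in A} lambda_S |B|/(|A| n)``,
    which equals the game-theoretic Shapley value of the split-diversity
    game.  By the efficiency axiom the values sum to the total split weight.
    """
    n = system.n
    if n < 2:
        raise ValueError("Shapley index requires at least 2 taxa")
    vals = dict.fromkeys(system.taxa.labels, 0.0)
    for sp, w in system.splits:
        for side, other in ((sp.side_a, sp.side_b), (sp.side_b, sp.side_a)):
            share = w * len(other) / (len(side) * n)
            for i in side:
                vals[system.taxa.labels[i]] += share
    return IndexVector(vals, "SH")


def expected_pd(system: WeightedSplitSystem, eps: ExtinctionProfile) -> float:
    """Expected future phylogenetic diversity under independent extinctions.

    A split survives iff at least one taxon survives on each side:

    ``E[PD] = sum_S lambda_S (1 - prod_{j in A} eps_j)(1 - prod_{k in B} eps_k)``.
    """
    eps_arr = eps.as_array(system.taxa)
    total = 0.0
    for sp, w in system.splits:
        pa = float(np.prod(eps_arr[list(sp.side_a)]))
        pb = float(np.prod(eps_arr[list(sp.side_b)]))
        total += w * (1.0 - pa) * (1.0 - pb)
    return total


def hed(system: WeightedSplitSystem, eps: ExtinctionProfile) -> IndexVector:
    """Heightened evolutionary distinctiveness of every taxon.

    ``HED(i)`` is the expected marginal contribution of taxon i: for each
    split containing i in side A, the split is "carried" by i alone when
    every other member of A is extinct and at least one member of B
    survives.  ``eps_i`` itself never enters ``HED(i)``.
    """
    eps_arr = eps.as_array(system.taxa)
    labels = system.taxa.labels
    vals = dict.fromkeys(labels, 0.0)
    for sp, w in system.splits:
        for side, other in ((sp.side_a, sp.side_b), (sp.side_b, sp.side_a)):
            p_side = float(np.prod(eps_arr[list(side)]))
            p_other_extinct = float(np.prod(eps_arr[list(other)]))
            surv_other = 1.0 - p_other_extinct
            for i in side:
                # prod over side \ {i}; recompute directly when eps_i == 0
                # to avoid dividing by zero.
                if eps_arr[i] > 0.0:
                    p_rest = p_side / eps_arr[i]
                else:
                    rest = [j for j in side if j != i]
                    p_rest = float(np.prod(eps_arr[rest])) if rest else 1.0
                vals[labels[i]] += w * p_rest * surv_other
    return IndexVector(vals, "HED")


def hedge(system: WeightedSplitSystem, eps: ExtinctionProfile) -> IndexVector:
    """HEDGE(i) = eps_i * HED(i).

    Identically the increase in expected PD obtained by changing taxon
    i's extinction probability from its current value to zero.
    """
    h = hed(system, eps)
    vals = {lab: eps[lab] * v for lab, v in h.items()}
    return IndexVector(vals, "HEDGE")


def rank_values(
    values: IndexVector | dict[str, float],
    kind: str | None = None,
) -> RankingTable:
    """Dense ordinal ranks 1..n, highest value first.

    Exact ties are broken by lexicographic label order and flagged on
    every member of the tied group.
    """
    kind = kind or getattr(values, "kind", "value")
    items = sorted(values.items(), key=lambda kv: (-kv[1], kv[0]))
    rows = []
    for pos, (lab, val) in enumerate(items, start=1):
        tied = any(
            _tie_eq(val, other_val)
            for other_lab, other_val in values.items()
            if other_lab != lab
        )
        rows.append(RankingRow(lab, {kind: val}, pos, None, tied))
    return RankingTable(rows)


def i_hedge(
    system: WeightedSplitSystem,
    eps: ExtinctionProfile,
    saved_pext: float = 0.001,
) -> RankingTable:
    """Iterative HEDGE ranking (I-HEDGE).

    Iteration k computes HEDGE under the current profile; the highest-
    scoring not-yet-ranked taxon receives rank k (exact ties broken
    lexicographically and flagged), and its extinction probability is
    then set to ``saved_pext`` — the taxon is treated as (all but)
    saved.  After n-1 iterations the single remaining taxon receives
    rank n.  The full HEDGE vector of every iteration is kept in
    ``iteration_trace``.
    """
    if not 0.0 <= saved_pext <= 1.0:
        raise ValueError(f"saved_pext must be in [0, 1], got {saved_pext}")
    eps.validate_for(system.taxa)
    n = system.n
    labels = list(system.taxa.labels)

    current = eps
    remaining = set(labels)
    rows: list[RankingRow] = []
    trace: list[dict[str, float]] = []
    sh = shapley(system)
    hed0 = hed(system, eps)
    hedge0 = hedge(system, eps)

    for k in range(1, n):
        hg = hedge(system, current)
        trace.append(dict(hg))
        cand = {lab: hg[lab] for lab in remaining}
        best = max(cand.values())
        tied_group = sorted(lab for lab, v in cand.items() if _tie_eq(v, best))
        pick = tied_group[0]
        rows.append(
            RankingRow(
                pick,
                {
                    "SH": sh[pick],
                    "HED": hed0[pick],
                    "HEDGE": hedge0[pick],
                    "IHEDGE_score": hg[pick],
                },
                k,
                iteration_picked=k,
                tied=len(tied_group) > 1,
            )
        )
        remaining.discard(pick)
        current = current.with_pext(pick, saved_pext)

    (last,) = remaining
    rows.append(
        RankingRow(
            last,
            {
                "SH": sh[last],
                "HED": hed0[last],
                "HEDGE": hedge0[last],
                "IHEDGE_score": trace[-1][last] if trace else 0.0,
            },
            n,
            iteration_picked=n,
            tied=False,
        )
    )
    return RankingTable(rows, iteration_trace=trace)


# ---------------------------------------------------------------------------
# IUCN Red List proxies
# ---------------------------------------------------------------------------

#: Default Red List category -> p(ext) proxy table.  Least Concern and
#: Near Threatened carry no published proxy here and deliberately require
#: an explicit user-supplied value.
DEFAULT_IUCN_TABLE: dict[str, float] = {
    "VU": 0.1,
    "EN": 0.667,
    "CR": 0.999,
    "EX": 1.0,
}

_IUCN_ALIASES = {
    "VULNERABLE": "VU",
    "ENDANGERED": "EN",
    "CRITICALLY ENDANGERED": "CR",
    "EXTINCT": "EX",
    "VU": "VU",
    "EN": "EN",
    "CR": "CR",
    "EX": "EX",
}


def iucn_to_pext(category: str, table: dict[str, float] | None = None) -> float:
    """Map an IUCN Red List category to an extinction probability.

    Accepts full names or the standard two-letter codes, case-insensitive.
    Unknown categories raise a ``KeyError`` listing the known ones.
    """
    table = DEFAULT_IUCN_TABLE if table is None else table
    key = str(category).strip().upper()
    key = _IUCN_ALIASES.get(key, key)
    if key not in table:
        known = sorted(table)
        raise KeyError(
            f"unknown IUCN category {category!r}; known categories: {known}"
        )
    return float(table[key])


# ---------------------------------------------------------------------------
# Rank comparison
# ---------------------------------------------------------------------------

def spearman_rank(ranks1: Sequence[float], ranks2: Sequence[float]) -> float:
    """Spearman's rank correlation between two rank vectors.

    For untied permutations of 1..n this equals
    ``1 - 6 sum(d^2) / (n (n^2 - 1))``; general inputs go through the
    standard tie-corrected (Pearson-on-ranks) formula.
    """
    r1 = np.asarray(ranks1, dtype=float)
    r2 = np.asarray(ranks2, dtype=float)
    if r1.shape != r2.shape:
        raise ValueError(f"length mismatch: {r1.shape} vs {r2.shape}")
    if r1.ndim != 1 or len(r1) < 2:
        raise ValueError("need two rank vectors of equal length >= 2")
    from scipy import stats

    rho = stats.spearmanr(r1, r2).statistic
    return float(rho)


def spearman_pvalue(
    ranks1: Sequence[float],
    ranks2: Sequence[float],
    *,
    exact_max_n: int = 10,
) -> tuple[float, str]:
    """Two-sided p-value for Spearman's rho.

    For ``n <= exact_max_n`` the exact permutation distribution (all n!
    orderings of one vector) is enumerated; otherwise the usual
    t-approximation is used.  Returns ``(p, method)`` with method one of
    ``"exact-permutation"`` or ``"t-approximation"``.
    """
    r1 = np.asarray(ranks1, dtype=float)
    r2 = np.asarray(ranks2, dtype=float)
    n = len(r1)
    obs = abs(spearman_rank(r1, r2))
    if n <= exact_max_n:
        # Permuting r2 preserves its tie structure, so Pearson-on-ranks is
        # a monotone function of the cross dot product; enumerate those.
        c1 = r1 - r1.mean()
        c2 = r2 - r2.mean()
        denom = math.sqrt(float(c1 @ c1) * float(c2 @ c2))
        if denom == 0.0:
            return 1.0, "exact-permutation"
        obs_dot = abs(float(c1 @ c2))
        count = 0
        total = 0
        chunk: list[tuple[float, ...]] = []
        for perm in itertools.permutations(c2):
            chunk.append(perm)
            if len(chunk) == 50000:
                dots = np.abs(np.asarray(chunk) @ c1)
                count += int((dots >= obs_dot - 1e-9).sum())
                total += len(chunk)
                chunk = []
        if chunk:
            dots = np.abs(np.asarray(chunk) @ c1)
            count += int((dots >= obs_dot - 1e-9).sum())
            total += len(chunk)
        return count / total, "exact-permutation"
    from scipy import stats

    p = stats.spearmanr(r1, r2).pvalue
    return float(p), "t-approximation"
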