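"""Sequence distances and pairwise population differentiation.

Implements the Kimura 2-parameter (K2P) distance, its gamma-corrected
variant for rate heterogeneity across sites, and the AMOVA-based
pairwise fixation index Phi_ST computed from inter-individual squared
distances — the standard pipeline for mitochondrial control-region
population data.

Gaps and ambiguous bases are removed pairwise: each sequence pair keeps
only the sites where both have an unambiguous A/C/G/T.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

from .core import DistanceMatrix

__all__ = [
    "SaturationError",
    "k2p_distance",
    "PopulationAlignment",
    "PhiStResult",
    "pairwise_phi_st",
]

_VALID = frozenset("ACGT")
_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


class SaturationError(ValueError):
    """Raised when substitution saturation makes the distance undefined
    (the argument of a log or fractional power is <= 0)."""


def _count_differences(seq1: str, seq2: str) -> tuple[int, int, int]:
    """(comparable sites, transitions, transversions) after pairwise deletion."""
    if len(seq1) != len(seq2):
        raise ValueError(
            f"sequences differ in length: {len(seq1)} vs {len(seq2)}"
        )
    n = ts = tv = 0
    for a, b in zip(seq1.upper(), seq2.upper()):
        if a not in _VALID or b not in _VALID:
            continue
        n += 1
        if a == b:
            continue
        if (a in _PURINES) == (b in _PURINES):
            ts += 1
        else:
            tv += 1
    return n, ts, tv


def k2p_distance(
    seq1: str, seq2: str, gamma_alpha: float | None = None
) -> float:
    """Kimura 2-parameter distance between two aligned sequences.

    With transition proportion P and transversion proportion Q over the
    retained sites:

    * ``gamma_alpha=None`` (equal rates):
      ``d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)``
    * ``gamma_alpha=a`` (gamma rates, shape a):
      ``d = a/2 [(1 - 2P - Q)^(-1/a) - 1] + a/4 [(1 - 2Q)^(-1/a) - 1]``

    Sites where either sequence has a gap or an ambiguous base are
    dropped (pairwise deletion).  Raises :class:`SaturationError` when
    the divergence is too large for the model, and ``ValueError`` when no
    comparable sites remain.
    """
    if gamma_alpha is not None and gamma_alpha <= 0:
        raise ValueError(f"gamma_alpha must be positive, got {gamma_alpha}")
    n, ts, tv = _count_differences(seq1, seq2)
    if n == 0:
        raise ValueError("no comparable sites (pairwise deletion removed all)")
    p = ts / n
    q = tv / n
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(
            f"substitution saturation: P={p:.4f}, Q={q:.4f} leave "
            "a non-positive argument in the distance formula"
        )
    if gamma_alpha is None:
        return float(-0.5 * np.log(w1) - 0.25 * np.log(w2))
    a = float(gamma_alpha)
    return float(
        (a / 2.0) * (w1 ** (-1.0 / a) - 1.0)
        + (a / 4.0) * (w2 ** (-1.0 / a) - 1.0)
    )


class PopulationAlignment:
    """Equal-length sequences grouped into named populations."""

    def __init__(self, populations: Mapping[str, Sequence[str]]):
        pops = {str(k): [str(s).upper() for s in v] for k, v in populations.items()}
        if not pops:
            raise ValueError("no populations")
        lengths = {len(s) for seqs in pops.values() for s in seqs}
        if len(lengths) > 1:
            raise ValueError(f"sequences differ in length: {sorted(lengths)}")
        if any(len(v) == 0 for v in pops.values()):
            empty = [k for k, v in pops.items() if not v]
            raise ValueError(f"populations with no sequences: {empty}")
        self.populations = pops
        self.length = lengths.pop() if lengths else 0

    @property
    def labels(self) -> list[str]:
        return list(self.populations)

    def sizes(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.populations.items()}

    def __repr__(self) -> str:
        return f"PopulationAlignment(pops={self.sizes()}, length={self.length})"


@dataclass
class PhiStResult:
    """Two-group AMOVA decomposition for one population pair.

    ``phi_st = sigma2_a / (sigma2_a + sigma2_b)`` whenever the total
    variance is positive; ``raw`` values may be negative (sampling noise
    around zero differentiation) and are clamped only where a
    dissimilarity is required downstream.
    """

    pop1: str
    pop2: str
    phi_st: float
    sigma2_a: float
    sigma2_b: float
    n_pairs_used: int
    undefined: bool = False
    p_value: float | None = None


def _two_group_amova(d2: np.ndarray, n1: int) -> tuple[float, float, float, bool]:
    """Variance components from a squared-distance matrix of two groups.

    ``d2`` holds squared inter-individual distances for all N = n1 + n2
    individuals, the first ``n1`` belonging to group 1.  Returns
    ``(phi_st, sigma2_a, sigma2_b, undefined)``.
    """
    n_tot = d2.shape[0]
    n2 = n_tot - n1
    # SS from ordered pairs: (1/(2N)) sum_ij d2 == (1/N) sum_{i<j} d2
    ss_total = d2.sum() / (2.0 * n_tot)
    ss_w1 = d2[:n1, :n1].sum() / (2.0 * n1)
    ss_w2 = d2[n1:, n1:].sum() / (2.0 * n2)
    ss_within = ss_w1 + ss_w2
    ss_among = ss_total - ss_within
    df_within = n_tot - 2
    if df_within <= 0:
        # two singleton groups: no within-group information
        sigma2_b = 0.0
    else:
        sigma2_b = ss_within / df_within
    n0 = (n_tot - (n1 * n1 + n2 * n2) / n_tot) / 1.0
    sigma2_a = (ss_among / 1.0 - sigma2_b) / n0
    denom = sigma2_a + sigma2_b
    if denom <= 0.0:
        return 0.0, sigma2_a, sigma2_b, True
    return sigma2_a / denom, sigma2_a, sigma2_b, False


def pairwise_phi_st(
    alignment: PopulationAlignment,
    gamma_alpha: float | None = 0.5,
    permutations: int = 0,
    seed: int | None = None,
) -> tuple[DistanceMatrix, dict[tuple[str, str], PhiStResult]]:
    """Pairwise Phi_ST between all population pairs.

    For each pair, a two-group AMOVA is run on the matrix of squared
    inter-individual K2P(gamma) distances:

    * ``SS_total = (1/(2N)) sum over ordered pairs d^2``
    * ``SS_within = sum over groups (1/(2 n_g)) sum over ordered
      within-group pairs d^2``
    * ``sigma2_b = SS_within / (N - 2)``,
      ``sigma2_a = (SS_among - sigma2_b) / n0`` with
      ``n0 = N - (n1^2 + n2^2)/N``
    * ``Phi_ST = sigma2_a / (sigma2_a + sigma2_b)``

    Individuals (not collapsed haplotypes) are the analysis units.
    Negative Phi_ST values are kept raw in the per-pair results and
    clamped to 0 in the returned :class:`DistanceMatrix`, which must be a
    dissimilarity for network construction.  Pairs where all distances
    vanish have Phi_ST undefined; they are flagged and reported as 0.

    With ``permutations > 0``, a permutation test (individuals shuffled
    between the two populations, seeded) attaches a p-value
    ``(hits + 1) / (permutations + 1)`` to each pair.
    """
    pops = alignment.labels
    if len(pops) < 2:
        raise ValueError("pairwise Phi_ST needs at least 2 populations")
    rng = np.random.default_rng(seed)

    mat = np.zeros((len(pops), len(pops)))
    results: dict[tuple[str, str], PhiStResult] = {}
    for (ia, pa), (ib, pb) in combinations(enumerate(pops), 2):
        seqs = alignment.populations[pa] + alignment.populations[pb]
        n1 = len(alignment.populations[pa])
        n_tot = len(seqs)
        d2 = np.zeros((n_tot, n_tot))
        for i in range(n_tot):
            for j in range(i + 1, n_tot):
                d = k2p_distance(seqs[i], seqs[j], gamma_alpha)
                d2[i, j] = d2[j, i] = d * d
        phi, s2a, s2b, undef = _two_group_amova(d2, n1)
        pval = None
        if permutations > 0 and not undef:
            hits = 0
            idx = np.arange(n_tot)
            for _ in range(permutations):
                rng.shuffle(idx)
                perm_d2 = d2[np.ix_(idx, idx)]
                phi_p, _, _, undef_p = _two_group_amova(perm_d2, n1)
                if not undef_p and phi_p >= phi - 1e-12:
                    hits += 1
            pval = (hits + 1) / (permutations + 1)
        results[(pa, pb)] = PhiStResult(
            pa, pb, phi, s2a, s2b,
            n_pairs_used=n_tot * (n_tot - 1) // 2,
            undefined=undef, p_value=pval,
        )
        mat[ia, ib] = mat[ib, ia] = max(phi, 0.0)
    return DistanceMatrix(pops, mat), results
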