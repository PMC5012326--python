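# Methods

## Split systems and the diversity model

The central object is a weighted split system over n taxa: bipartitions
S = (A, B) with weights λ_S ≥ 0 in the units of the input distances.
The phylogenetic diversity (PD) of a subset Y of taxa is the total
weight of splits separated by Y (members of Y on both sides). This is
the unrooted convention: PD of a singleton is 0, and on a tree PD(Y) is
the length of the spanning subtree of Y. Two consequences worth
spelling out because they shape the indices:

- the split distance d(i, j) = Σ λ_S over splits separating i and j
  generalizes patristic distance, and
- a split "survives" into the future iff at least one taxon survives on
  *each* side; a sole survivor carries no diversity by itself. In
  particular, as all extinction probabilities approach 1, HED(i) tends
  to 0 (linearly, with slope Σ_S λ_S·|side opposite i|), not to the
  total weight of splits touching i.

Trees are converted to split systems edge-by-edge. Split systems are
unrooted objects, so a degree-2 root is suppressed: its two incident
edges induce the same bipartition and their lengths are summed.
Zero-length edges are kept as weight-0 splits (they never affect any
index). Multifurcations are accepted as-is; each edge still gives one
split.

## Indices

SH, expected PD, HED and HEDGE use the closed forms stated in the
README. They are exact (no sampling), O(#splits · n) per evaluation,
and are cross-checked in the test suite against two independent
brute-force oracles: full enumeration of all n! arrival orders for the
Shapley value (n ≤ 8) and of all 2^n survival outcomes for expected PD
(n ≤ 15). HEDGE is additionally verified against its defining identity
HEDGE(i) = E[PD | ε_i := 0] − E[PD] for every taxon of every tested
system. The oracle size caps keep full-enumeration runs in the
seconds-to-minutes range on one CPU.

I-HEDGE ranks the top-HEDGE taxon, sets its ε to `saved_pext` (default
0.001, exposed as a flag; 0 is allowed and gives the same ranking on
generic systems), and recomputes until one taxon remains. Extinct taxa
(ε = 1) participate fully and can be "saved" — restoring an extinct
lineage is the method's motivating use case. The full HEDGE vector of
every iteration is retained so a user can audit why the order came out
as it did.

Ties: exact ties (equality to 12 significant digits) are broken by
lexicographic label order and *flagged* in every output rather than
hidden, so other considerations can be brought to bear on tied taxa.

IUCN Red List proxies for ε are provided (VU = 0.1, EN = 0.667,
CR = 0.999, EX = 1.0, with full-name and two-letter aliases). Least
Concern and Near Threatened have no widely used proxy value and
deliberately require an explicit user-supplied number. The tool never
assumes a default extinction profile; the flat ε = 0.5 used for
intensively managed taxa in the tortoise analysis is a documented
preset of `scripts/external_validation.py`, not a package default.

## Sequence distances and Φ_ST

K2P distances separate transition proportion P from transversion
proportion Q over the sites where both sequences have an unambiguous
base (pairwise deletion — the conventional choice for control-region
data, and the default of the standard AMOVA software). The
gamma-corrected form with shape α replaces each logarithm by the
corresponding power-law term; α = 0.5 is the package default, the
empirical value for control-region sequences, and α → ∞ recovers the
equal-rates formula. Saturation (a non-positive log/power argument)
raises an explicit error instead of returning infinity.

Pairwise Φ_ST is a two-group AMOVA on squared inter-individual
distances, with individuals (not collapsed haplotypes) as units:
SS_total = (1/2N)·Σ over ordered pairs d², SS_within analogously per
group, σ²_b = SS_within/(N−2), σ²_a = (SS_among − σ²_b)/n₀ with
n₀ = N − (n₁² + n₂²)/N, and Φ_ST = σ²_a/(σ²_a + σ²_b). Negative values
(sampling noise around zero differentiation) are preserved raw in the
per-pair results and clamped to 0 only in the matrix handed to network
construction, which requires a dissimilarity. Pairs with no molecular
variance at all are flagged undefined and reported as 0. A permutation
test (individuals shuffled between the two populations, seeded,
p = (hits+1)/(perms+1)) is available but nothing downstream uses it.

## NeighbourNet

Stage 1 (ordering) follows the agglomerative scheme: a neighbour-joining
criterion Q(C_i, C_j) = (m−2)·d(C_i, C_j) − Σ_k d(C_i, C_k) − Σ_k
d(C_j, C_k) over cluster-average distances picks two clusters; the same
criterion applied to the mixed unit set (members of the two chosen
clusters as individuals, every other cluster as one unit) picks the
node pair to link. Linked nodes form paths; a path of more than two
nodes is reduced, leftmost triple first, to two fresh nodes via the
2/3–1/3 distance-update rules, and the reduction stack is unwound at
the end to expand the final 2–3 node cycle into the full circular
ordering. Equal selection criteria are resolved toward the
lexicographically smallest index pair, making the construction
deterministic without seeds.

Stage 2 (weights) fits all n(n−1)/2 interval splits of the ordering to
the input matrix by ordinary (unweighted) least squares under
non-negativity, using the active-set NNLS algorithm; at the problem
sizes this package targets (tens of taxa, a few hundred candidate
splits) no specialized solver is needed. Splits with fitted weight at
or below `weight_threshold` (default 1e-6 in input-distance units — the
convention of discarding numerically zero splits) are dropped; pendant
splits carry through to the indices like any other split. For a fixed
circular ordering the interval-split design matrix is nonsingular, so
circular-decomposable inputs — including all additive tree metrics —
are recovered exactly (verified to 1e-6, typically ~1e-14), and
dropping sub-threshold splits can only increase the residual.

## Synthetic data

The generators produce seeded random binary trees (uniform joins,
exponential branch lengths), random circular split systems (random arcs
of a random ordering, weights bounded away from 0 so generate-and-refit
comparisons are well-posed), and population alignments evolved by
per-site substitution from a common ancestor: one ancestor per
population at divergence rate d, individuals at a small within-
population rate, transitions favoured 4:1. This emulates the structure
that matters to the distance/Φ_ST/network stages — graded
between-population divergence with controllable within-population
diversity, so Φ_ST rises from ≈0 (d = 0) towards 1 (fixed differences).
It does not emulate recombination, indels, site-rate heterogeneity,
selection or realistic coalescent genealogies; passing tests demonstrate
the correctness of the computations, not the adequacy of any of those
simplifications for real data.

A 12-row reference table of published SH and I-HEDGE ranks for the
Galápagos giant tortoise radiation is embedded for desk-scale
concordance checks (Spearman ρ = 0.8601, maximum displacement 4). The
full sequence-level re-analysis needs an external DRYAD download and
lives in `scripts/external_validation.py`.

## Numerical and design choices

- Exact-tie detection uses a relative tolerance of 1e-12; analytically
  equal scores computed along different float paths register as ties,
  genuinely distinct ones essentially never do.
- Spearman's ρ uses the tie-corrected (Pearson-on-ranks) formula. The
  p-value uses the exact permutation distribution for n ≤ 10 and the
  t-approximation above, and is labelled with the method used; at
  n = 12 the two rank columns of the reference table give ρ = 0.8601,
  p ≈ 3.3e-4 by the t-approximation.
- The Φ_ST permutation p-value uses the (hits+1)/(perms+1) estimator.
- Distance matrices are validated (symmetry to 1e-8, zero diagonal,
  no NaN, non-negativity) and then exactly symmetrized; readers reject
  malformed files rather than repairing them.
- Problem sizes in the test suite and acceptance script (oracle checks
  at n ≤ 7 / n ≤ 12, NeighbourNet recovery at n ≤ 20, pipelines on 4–5
  populations of 4–6 individuals × 200–300 bp) were chosen to exercise
  every code path at full-enumeration fidelity while keeping a complete
  run in the minutes range on a single CPU.

## Known limitations

- Φ_ST is limited to two-group AMOVA (pairwise); no hierarchical
  designs.
- Only the K2P family of distances is built in.
- NeighbourNet here produces the split system, not a planar drawing.
- The ranking treats extinction events as independent across taxa;
  correlated threats (shared catastrophes) are out of scope.
- I-HEDGE with `saved_pext = 0` can in principle differ from 0.001 on
  contrived systems where a taxon's entire score rides on splits whose
  opposite side is fully "saved"; on generic random systems the
  rankings coincide (tested), and any counterexample found in use
  should be assessed via the per-iteration trace.
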