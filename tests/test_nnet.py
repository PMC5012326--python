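"""NeighbourNet: circular orderings and non-negative split weights."""

import numpy as np
import pytest

from ihedge.core import DistanceMatrix, Split, TaxonSet, WeightedSplitSystem, splits_from_tree
from ihedge.nnet import (
    CircularOrdering,
    circular_interval_splits,
    neighbor_net,
    nnls_split_weights,
)
from ihedge.simulate import random_circular_system, random_tree


def is_interval(split: Split, ordering: CircularOrdering) -> bool:
    pos = {t: k for k, t in enumerate(ordering.ordering)}
    n = ordering.n
    for side in (split.side_a, split.side_b):
        ps = sorted(pos[t] for t in side)
        runs = sum(
            1 for a, b in zip(ps, ps[1:] + [ps[0] + n]) if b - a > 1
        )
        if runs <= 1:
            return True
    return False


class TestCircularOrdering:
    def test_must_be_permutation(self):
        with pytest.raises(ValueError):
            CircularOrdering((0, 0, 1))

    def test_canonical_fixes_rotation_and_reflection(self):
        a = CircularOrdering((2, 0, 3, 1)).canonical()
        b = CircularOrdering((3, 0, 2, 1)).canonical()  # reflection of a
        assert a.ordering[0] == 0
        assert a == b

    def test_interval_split_count(self):
        order = CircularOrdering((0, 1, 2, 3, 4))
        assert len(circular_interval_splits(order)) == 10


class TestNnlsWeights:
    def test_single_split_recovered(self):
        taxa = TaxonSet(["a", "b", "c", "d"])
        system = WeightedSplitSystem(taxa, [(Split.of({0, 1}, 4), 2.5)])
        order = CircularOrdering((0, 1, 2, 3))
        w = nnls_split_weights(order, system.distance_matrix())
        splits = circular_interval_splits(order)
        recovered = {sp: x for sp, x in zip(splits, w) if x > 1e-10}
        assert recovered == {Split.of({0, 1}, 4): pytest.approx(2.5)}

    def test_all_zero_distances(self):
        D = DistanceMatrix(["a", "b", "c"], np.zeros((3, 3)))
        w = nnls_split_weights(CircularOrdering((0, 1, 2)), D)
        assert np.all(w == 0.0)

    def test_generate_and_refit(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 10))
            system, order = random_circular_system(n, rng)
            ordering = CircularOrdering(tuple(order))
            w = nnls_split_weights(ordering, system.distance_matrix())
            fitted = {
                sp: x
                for sp, x in zip(circular_interval_splits(ordering), w)
                if x > 1e-8
            }
            true = {sp: x for sp, x in system.splits}
            assert set(fitted) == set(true)
            for sp in true:
                assert fitted[sp] == pytest.approx(true[sp], abs=1e-8)

    def test_dimension_mismatch(self):
        D = DistanceMatrix(["a", "b", "c"], np.zeros((3, 3)))
        with pytest.raises(ValueError, match="does not match"):
            nnls_split_weights(CircularOrdering((0, 1)), D)


class TestNeighborNet:
    def test_two_taxa(self):
        D = DistanceMatrix(["A", "B"], np.array([[0.0, 5.0], [5.0, 0.0]]))
        system, ordering = neighbor_net(D)
        assert len(system) == 1
        assert system.split_distance("A", "B") == pytest.approx(5.0)

    def test_quartet_tree_metric_recovered_exactly(self, quartet_newick):
        tree_system = splits_from_tree(quartet_newick)
        system, ordering = neighbor_net(tree_system.distance_matrix())
        true = {sp: w for sp, w in tree_system.splits}
        got = {sp: w for sp, w in system.splits}
        assert set(got) == set(true)
        for sp, w in true.items():
            assert got[sp] == pytest.approx(w, abs=1e-9)

    def test_box_both_incompatible_splits_recovered(self):
        taxa = TaxonSet(["A", "B", "C", "D"])
        generating = WeightedSplitSystem(
            taxa,
            [(Split.of({0, 1}, 4), 1.0), (Split.of({1, 2}, 4), 1.0)]
            + [(Split.of({i}, 4), 1.0) for i in range(4)],
        )
        system, _ = neighbor_net(generating.distance_matrix())
        got = {sp: w for sp, w in system.splits}
        assert got.keys() == {sp for sp, _ in generating.splits}
        assert all(w == pytest.approx(1.0, abs=1e-9) for w in got.values())

    def test_random_tree_metrics_recovered(self, rng):
        for _ in range(8):
            n = int(rng.integers(4, 21))
            tree_system = splits_from_tree(random_tree(n, rng))
            D = tree_system.distance_matrix()
            system, ordering = neighbor_net(D)
            true = {sp: w for sp, w in tree_system.splits}
            got = {sp: w for sp, w in system.splits}
            assert set(got) == set(true)
            for sp, w in true.items():
                assert got[sp] == pytest.approx(w, abs=1e-6)
            # split distances round-trip the input matrix
            labels = list(system.taxa)
            for i, a in enumerate(labels):
                for b in labels[i + 1 :]:
                    assert system.split_distance(a, b) == pytest.approx(
                        D[(a, b)], abs=1e-6
                    )

    def test_every_split_is_an_interval_of_the_ordering(self, rng):
        # includes non-decomposable (noisy) matrices
        n = 9
        base = splits_from_tree(random_tree(n, rng)).distance_matrix()
        noise = rng.uniform(0, 0.3, size=(n, n))
        noisy = base.values + noise + noise.T
        np.fill_diagonal(noisy, 0.0)
        system, ordering = neighbor_net(DistanceMatrix(base.labels, noisy))
        for sp, _ in system.splits:
            assert is_interval(sp, ordering)

    def test_residual_never_improves_when_dropping_splits(self, rng):
        n = 8
        base = splits_from_tree(random_tree(n, rng)).distance_matrix()
        noise = rng.uniform(0, 0.5, size=(n, n))
        noisy_v = base.values + noise + noise.T
        np.fill_diagonal(noisy_v, 0.0)
        D = DistanceMatrix(base.labels, noisy_v)

        def residual(threshold):
            system, _ = neighbor_net(D, weight_threshold=threshold)
            fit = system.distance_matrix()
            return float(((fit.values - D.values) ** 2).sum())

        r_full, r_cut = residual(0.0), residual(0.05)
        assert r_cut >= r_full - 1e-12

    def test_permutation_equivariance(self, rng):
        n = 7
        system0, _ = random_circular_system(n, rng)
        D = system0.distance_matrix()
        perm = list(rng.permutation(n))
        relabelled = DistanceMatrix(
            [D.labels[p] for p in perm],
            D.values[np.ix_(perm, perm)],
        )
        s1, _ = neighbor_net(D)
        s2, _ = neighbor_net(relabelled)
        d1 = {frozenset(map(frozenset, ((s.side_a), (s.side_b)))): w for s, w in s1.splits}

        def as_labelsets(system):
            out = {}
            for sp, w in system.splits:
                key = frozenset(
                    frozenset(system.taxa.labels[i] for i in side)
                    for side in (sp.side_a, sp.side_b)
                )
                out[key] = w
            return out

        a1, a2 = as_labelsets(s1), as_labelsets(s2)
        assert set(a1) == set(a2)
        for k in a1:
            assert a1[k] == pytest.approx(a2[k], abs=1e-8)

    def test_rejects_bad_matrices(self):
        with pytest.raises(ValueError):
            neighbor_net(DistanceMatrix(["a"], np.zeros((1, 1))))
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b"], np.array([[0, 1.0], [2.0, 0]]))
        with pytest.raises(ValueError, match="NaN"):
            DistanceMatrix(["a", "b"], np.full((2, 2), np.nan))
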