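"""Shapley, expected PD, HED/HEDGE, I-HEDGE, IUCN proxies, Spearman."""

import numpy as np
import pytest

from ihedge.core import ExtinctionProfile, Split, TaxonSet, WeightedSplitSystem, splits_from_tree
from ihedge.indices import (
    expected_pd,
    hed,
    hedge,
    i_hedge,
    iucn_to_pext,
    rank_values,
    shapley,
    spearman_pvalue,
    spearman_rank,
)
from ihedge.nnet import neighbor_net
from ihedge.simulate import (
    brute_force_shapley,
    enumerate_expected_pd,
    galapagos_rankings,
    random_circular_system,
    random_profile,
    random_tree,
)


def flat_profile(system, eps):
    return ExtinctionProfile({lab: eps for lab in system.taxa})


class TestShapley:
    def test_two_taxa_symmetry_efficiency(self):
        system = WeightedSplitSystem(
            TaxonSet(["a", "b"]), [(Split.of({0}, 2), 3.0)]
        )
        sh = shapley(system)
        assert sh["a"] == pytest.approx(1.5) and sh["b"] == pytest.approx(1.5)

    def test_star_closed_form_matches_permutation_oracle(self, star3):
        sh = shapley(star3)
        assert [sh[t] for t in star3.taxa] == pytest.approx([1.5, 2.0, 2.5])
        assert brute_force_shapley(star3) == pytest.approx(dict(sh))

    def test_matches_brute_force_on_random_systems(self, rng):
        for _ in range(25):
            n = int(rng.integers(3, 8))
            system, _ = random_circular_system(n, rng)
            fast = shapley(system)
            slow = brute_force_shapley(system)
            for lab in system.taxa:
                assert fast[lab] == pytest.approx(slow[lab], rel=1e-9, abs=1e-12)

    def test_efficiency_axiom(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 15))
            system, _ = random_circular_system(n, rng)
            total = system.total_diversity()
            assert sum(shapley(system).values()) == pytest.approx(total, rel=1e-10)


class TestExpectedPd:
    def test_degenerate_profiles(self, star3):
        assert expected_pd(star3, flat_profile(star3, 0.0)) == pytest.approx(6.0)
        assert expected_pd(star3, flat_profile(star3, 1.0)) == 0.0

    def test_star_half_extinction(self, star3):
        eps = flat_profile(star3, 0.5)
        assert expected_pd(star3, eps) == pytest.approx(2.25)
        assert enumerate_expected_pd(star3, eps) == pytest.approx(2.25)

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(25):
            n = int(rng.integers(2, 13))
            system, _ = random_circular_system(n, rng)
            eps = random_profile(system.taxa, rng)
            assert expected_pd(system, eps) == pytest.approx(
                enumerate_expected_pd(system, eps), rel=1e-10, abs=1e-12
            )

    def test_missing_taxon_is_an_error(self, star3):
        with pytest.raises(KeyError):
            expected_pd(star3, ExtinctionProfile({"t1": 0.5, "t2": 0.5}))


class TestHedAndHedge:
    def test_two_taxon_closed_form(self):
        system = WeightedSplitSystem(
            TaxonSet(["a", "b"]), [(Split.of({0}, 2), 1.0)]
        )
        h = hed(system, ExtinctionProfile({"a": 0.5, "b": 0.5}))
        assert h["a"] == pytest.approx(0.5) and h["b"] == pytest.approx(0.5)

    def test_star_values(self, star3):
        eps = flat_profile(star3, 0.5)
        h = hed(star3, eps)
        assert [h[t] for t in star3.taxa] == pytest.approx([2.0, 2.5, 3.0])
        hg = hedge(star3, eps)
        assert [hg[t] for t in star3.taxa] == pytest.approx([1.0, 1.25, 1.5])

    def test_hed_independent_of_own_pext(self, star3):
        base = hed(star3, flat_profile(star3, 0.5))
        for own in (0.0, 0.2, 0.999):
            eps = flat_profile(star3, 0.5).with_pext("t2", own)
            assert hed(star3, eps)["t2"] == pytest.approx(base["t2"])

    def test_hedge_is_expected_pd_gain_from_saving(self, rng):
        """HEDGE(i) == E[PD | eps_i := 0] - E[PD], the definitional identity."""
        for _ in range(10):
            n = int(rng.integers(2, 10))
            system, _ = random_circular_system(n, rng)
            eps = random_profile(system.taxa, rng)
            hg = hedge(system, eps)
            base = expected_pd(system, eps)
            for lab in system.taxa:
                gain = expected_pd(system, eps.with_pext(lab, 0.0)) - base
                assert hg[lab] == pytest.approx(gain, rel=1e-9, abs=1e-12)

    def test_hedge_limits(self, star3):
        eps = flat_profile(star3, 0.5).with_pext("t1", 0.0).with_pext("t3", 1.0)
        hg = hedge(star3, eps)
        assert hg["t1"] == 0.0  # already safe: no gain
        assert hg["t3"] == pytest.approx(hed(star3, eps)["t3"])  # extinct: full gain

    def test_hed_near_certain_extinction_limit(self, rng):
        """As all eps -> 1, HED(i) -> 0 linearly with slope
        sum over splits touching i of lambda_S * |other side|: a split still
        needs a survivor on BOTH sides, so a sole survivor carries nothing,
        and the leading term counts single-survivor rescues across from i."""
        system, _ = random_circular_system(6, rng)
        delta = 1e-7
        h = hed(system, flat_profile(system, 1.0 - delta))
        for idx, lab in enumerate(system.taxa):
            slope = sum(
                w * len(sp.other_side(idx))
                for sp, w in system.splits
            )
            assert h[lab] == pytest.approx(delta * slope, rel=1e-5)
        assert all(v == 0.0 for v in hed(system, flat_profile(system, 1.0)).values())


class TestIHedge:
    def test_star_iteration_order_and_trace(self, star3):
        table = i_hedge(star3, flat_profile(star3, 0.5))
        assert [r.label for r in table.by_rank()] == ["t3", "t2", "t1"]
        # round 1 is plain HEDGE; round 2 reflects t3 being saved
        assert table.iteration_trace[0]["t3"] == pytest.approx(1.5)
        assert table.iteration_trace[1]["t2"] == pytest.approx(1.749, abs=1e-3)
        assert table.iteration_trace[1]["t1"] == pytest.approx(1.2495, abs=1e-3)

    def test_symmetric_star_ties_flagged_lexicographic(self):
        taxa = TaxonSet(["b", "a", "c"])
        system = WeightedSplitSystem(
            taxa, [(Split.of({i}, 3), 1.0) for i in range(3)]
        )
        eps = ExtinctionProfile({t: 0.5 for t in taxa})
        table = i_hedge(system, eps)
        assert [r.label for r in table.by_rank()] == ["a", "b", "c"]
        assert all(r.tied for r in table.by_rank()[:-1])

    def test_first_pick_is_argmax_of_plain_hedge(self, rng):
        for _ in range(5):
            system, _ = random_circular_system(7, rng)
            eps = random_profile(system.taxa, rng)
            table = i_hedge(system, eps)
            assert table.by_rank()[0].label == hedge(system, eps).argmax()

    def test_saved_pext_zero_gives_same_ranking_generically(self, rng):
        for _ in range(10):
            system, _ = random_circular_system(8, rng)
            eps = random_profile(system.taxa, rng)
            r1 = [r.label for r in i_hedge(system, eps, saved_pext=0.001).by_rank()]
            r0 = [r.label for r in i_hedge(system, eps, saved_pext=0.0).by_rank()]
            assert r1 == r0

    def test_representation_independence(self, rng):
        """Indices agree whether the system comes from the tree directly or
        from refitting the tree's distance matrix."""
        nwk = random_tree(8, rng)
        from_tree = splits_from_tree(nwk)
        refit, _ = neighbor_net(from_tree.distance_matrix())
        eps = random_profile(from_tree.taxa, rng)
        assert dict(shapley(refit)) == pytest.approx(dict(shapley(from_tree)), abs=1e-8)
        assert dict(hedge(refit, eps)) == pytest.approx(
            dict(hedge(from_tree, eps)), abs=1e-8
        )

    def test_invalid_saved_pext(self, star3):
        with pytest.raises(ValueError):
            i_hedge(star3, flat_profile(star3, 0.5), saved_pext=1.5)


class TestIucnProxies:
    @pytest.mark.parametrize(
        "category,expected",
        [
            ("Vulnerable", 0.1),
            ("Endangered", 0.667),
            ("Critically Endangered", 0.999),
            ("EX", 1.0),
            ("vu", 0.1),
            ("CR", 0.999),
        ],
    )
    def test_default_table(self, category, expected):
        assert iucn_to_pext(category) == expected

    def test_unknown_category_lists_known(self):
        with pytest.raises(KeyError, match="known categories"):
            iucn_to_pext("Least Concern")


class TestSpearman:
    def test_published_tortoise_rank_columns(self):
        g = galapagos_rankings()
        assert spearman_rank(g["sh_rank"], g["ihedge_rank"]) == pytest.approx(
            0.8601, abs=5e-5
        )

    def test_extremes(self):
        assert spearman_rank([1, 2, 3, 4], [1, 2, 3, 4]) == pytest.approx(1.0)
        assert spearman_rank([1, 2, 3, 4], [4, 3, 2, 1]) == pytest.approx(-1.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            spearman_rank([1, 2, 3], [1, 2])

    def test_exact_permutation_pvalue_small_n(self):
        # |rho| = 1 is achieved by exactly the identity and the reversal
        p, method = spearman_pvalue([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert method == "exact-permutation"
        assert p == pytest.approx(2 / 120)

    def test_t_approximation_used_for_large_n(self):
        r1 = list(range(1, 13))
        p, method = spearman_pvalue(r1, r1[::-1])
        assert method == "t-approximation"
        assert p < 1e-6


class TestRankValues:
    def test_dense_ranks_and_tie_flags(self):
        table = rank_values({"a": 2.0, "b": 3.0, "c": 2.0}, kind="SH")
        assert table.rank_of("b") == 1
        assert table.rank_of("a") == 2 and table.rank_of("c") == 3
        flags = {r.label: r.tied for r in table.rows}
        assert flags == {"a": True, "c": True, "b": False}
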