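"""Genotype coding, hybrid deduction, marker QC and kinship construction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hybridgs import (GenotypeMatrix, InvalidGenotypeError, MarkerFilterSpec,
                      build_hybrid_matrix, compute_dominance_kinship,
                      compute_kinship, deduce_hybrid_code, filter_markers,
                      hybrid_id, impute_mean)
from hybridgs.designs import ParentPanel, half_diallel

from .conftest import random_genotypes


class TestDeduceHybridCode:
    @pytest.mark.parametrize(
        "p1,p2,expected",
        [
            (-1, 0, -0.5),   # A1A1 x A1A2
            (1, 0, 0.5),     # A2A2 x A1A2
            (0, 0, 0.0),     # both parents residually heterozygous
            (-1, -1, -1.0),  # identical homozygotes breed true
            (1, 1, 1.0),
            (-1, 1, 0.0),    # opposite homozygotes give a full heterozygote
        ],
    )
    def test_parental_mean(self, p1, p2, expected):
        assert deduce_hybrid_code(p1, p2) == expected

    def test_missing_parent_propagates(self):
        assert np.isnan(deduce_hybrid_code(float("nan"), 1))
        assert np.isnan(deduce_hybrid_code(-1, float("nan")))

    @pytest.mark.parametrize("bad", [0.5, -0.5, 2, -3])
    def test_invalid_code_rejected(self, bad):
        with pytest.raises(InvalidGenotypeError):
            deduce_hybrid_code(bad, 0)

    @given(st.sampled_from([-1, 0, 1]), st.sampled_from([-1, 0, 1]))
    def test_symmetric_in_parents(self, a, b):
        assert deduce_hybrid_code(a, b) == deduce_hybrid_code(b, a)

    @given(st.sampled_from([-1, 1]))
    def test_selfing_inbred_reproduces_parent(self, a):
        assert deduce_hybrid_code(a, a) == a


class TestBuildHybridMatrix:
    def test_marker_wise_mean(self):
        parents = GenotypeMatrix([[-1, 1], [1, 1]], ["m1", "m2"], ["P1", "P2"])
        H = build_hybrid_matrix(parents, [("P1", "P2")])
        assert H.individual_ids == ["P1_x_P2"]
        np.testing.assert_array_equal(H.codes[:, 0], [0.0, 1.0])

    def test_half_diallel_of_three(self, rng):
        parents = random_genotypes(rng, m=5, n=3, ids_prefix="P")
        crosses = [(a, b) for i, a in enumerate(parents.individual_ids)
                   for b in parents.individual_ids[i + 1:]]
        H = build_hybrid_matrix(parents, crosses)
        assert H.n_individuals == 3

    def test_within_group_diallel_of_21_parents_gives_100(self, rng):
        ids = [f"G{i}" for i in range(10)] + [f"X{i}" for i in range(11)]
        group = {p: ("Geng" if p.startswith("G") else "Xian") for p in ids}
        crosses = half_diallel(ParentPanel(ids, group), within_groups_only=True)
        parents = GenotypeMatrix(rng.choice([-1.0, 1.0], size=(4, 21)),
                                 [f"m{k}" for k in range(4)], ids)
        H = build_hybrid_matrix(parents, [(c.female, c.male) for c in crosses])
        assert H.n_individuals == 100

    def test_duplicate_cross_warns_and_deduplicates(self, rng):
        parents = random_genotypes(rng, m=3, n=2, ids_prefix="P")
        with pytest.warns(UserWarning, match="duplicate"):
            H = build_hybrid_matrix(parents, [("P0", "P1"), ("P1", "P0")])
        assert H.n_individuals == 1

    def test_unknown_parent_raises(self, rng):
        parents = random_genotypes(rng, m=3, n=2, ids_prefix="P")
        with pytest.raises(KeyError, match="unknown parent"):
            build_hybrid_matrix(parents, [("P0", "P9")])

    def test_hybrid_id_order_invariant(self):
        assert hybrid_id("B", "A") == hybrid_id("A", "B") == "A_x_B"


class TestFilterMarkers:
    def test_maf_strictly_above_threshold_kept(self):
        G = GenotypeMatrix([[-1, -1, -1, -1, -1, 1]], ["m1"], list("abcdef"))
        out, rep = filter_markers(G, MarkerFilterSpec(maf_min=0.1))
        assert out.n_markers == 1 and rep.n_failed_maf == 0  # MAF 1/6 > 0.1

    def test_missingness_threshold(self):
        codes = np.array([[np.nan, np.nan, np.nan, -1, 1, -1, 1, -1, 1, 1],
                          [-1, 1, -1, 1, -1, 1, -1, 1, -1, 1]])
        G = GenotypeMatrix(codes, ["m1", "m2"], [f"i{i}" for i in range(10)])
        out, rep = filter_markers(G, MarkerFilterSpec(missing_max=0.25))
        assert out.marker_ids == ["m2"]
        assert rep.n_failed_missing == 1

    def test_monomorphic_marker_removed(self):
        G = GenotypeMatrix([[-1, -1, -1], [-1, 1, 1]], ["m1", "m2"], list("abc"))
        out, rep = filter_markers(G, MarkerFilterSpec(maf_min=0.0))
        assert out.marker_ids == ["m2"]  # MAF 0 is not > 0

    def test_all_removed_raises(self):
        G = GenotypeMatrix([[-1, -1, -1]], ["m1"], list("abc"))
        with pytest.raises(ValueError, match="empty panel"):
            filter_markers(G, MarkerFilterSpec(maf_min=0.1))

    def test_idempotent(self, rng):
        G = random_genotypes(rng, m=50, n=20)
        spec = MarkerFilterSpec(maf_min=0.2)
        once, _ = filter_markers(G, spec)
        twice, rep = filter_markers(once, spec)
        assert twice.marker_ids == once.marker_ids
        assert rep.n_kept == rep.n_input


class TestImputeMean:
    def test_missing_replaced_by_marker_mean(self):
        G = GenotypeMatrix([[-1, 1, np.nan], [1, 1, np.nan]], ["m1", "m2"], list("abc"))
        out = impute_mean(G)
        assert out.codes[0, 2] == 0.0
        assert out.codes[1, 2] == 1.0
        assert not out.has_missing()

    def test_identity_without_missing(self, rng):
        G = random_genotypes(rng)
        np.testing.assert_array_equal(impute_mean(G).codes, G.codes)

    def test_entirely_missing_marker_raises(self):
        G = GenotypeMatrix([[np.nan, np.nan]], ["m1"], list("ab"))
        with pytest.raises(ValueError, match="entirely missing"):
            impute_mean(G)


class TestKinship:
    def test_single_marker_outer_product(self):
        G = GenotypeMatrix([[1, -1]], ["m1"], ["a", "b"])
        K = compute_kinship(G)
        np.testing.assert_array_equal(K.values, [[1, -1], [-1, 1]])

    def test_all_zero_codes(self):
        G = GenotypeMatrix(np.zeros((3, 4)), ["m1", "m2", "m3"], list("abcd"))
        np.testing.assert_array_equal(compute_kinship(G).values, np.zeros((4, 4)))

    def test_matches_bruteforce_sum_of_outer_products(self, rng):
        G = random_genotypes(rng, m=20, n=10, codes=(-1.0, -0.5, 0.0, 0.5, 1.0))
        K = compute_kinship(G)
        expected = np.zeros((10, 10))
        for k in range(20):
            z = G.codes[k]
            expected += np.outer(z, z)
        np.testing.assert_allclose(K.values, expected / 20, atol=1e-12)
        assert K.is_psd()

    def test_column_permutation_permutes_kinship(self, rng):
        G = random_genotypes(rng, m=15, n=6)
        perm = rng.permutation(6)
        Gp = GenotypeMatrix(G.codes[:, perm], G.marker_ids,
                            [G.individual_ids[i] for i in perm])
        K, Kp = compute_kinship(G), compute_kinship(Gp)
        np.testing.assert_allclose(Kp.values, K.values[np.ix_(perm, perm)], atol=1e-12)

    def test_linear_in_markers(self, rng):
        G = random_genotypes(rng, m=5, n=8)
        K = compute_kinship(G)
        singles = [compute_kinship(GenotypeMatrix(G.codes[[k]], [G.marker_ids[k]],
                                                  G.individual_ids)).values
                   for k in range(5)]
        np.testing.assert_allclose(K.values, np.mean(singles, axis=0), atol=1e-12)

    def test_missing_rejected(self):
        G = GenotypeMatrix([[np.nan, 1]], ["m1"], ["a", "b"])
        with pytest.raises(ValueError, match="impute"):
            compute_kinship(G)

    def test_centered_variant_differs(self, rng):
        G = random_genotypes(rng, m=30, n=8, codes=(-1.0, -1.0, -1.0, 1.0))
        K = compute_kinship(G)
        Kc = compute_kinship(G, center=True)
        assert not np.allclose(K.values, Kc.values)
        assert Kc.is_psd()


class TestDominanceKinship:
    def test_heterozygosity_indicator(self):
        G = GenotypeMatrix([[0, 1]], ["m1"], ["a", "b"])
        KD = compute_dominance_kinship(G)
        np.testing.assert_array_equal(KD.values, [[1, 0], [0, 0]])

    def test_fully_homozygous_panel_gives_zero(self, rng):
        G = random_genotypes(rng, m=10, n=5, codes=(-1.0, 1.0))
        assert not compute_dominance_kinship(G).values.any()

    def test_half_codes_map_to_half_heterozygosity(self):
        G = GenotypeMatrix([[0.5, -0.5]], ["m1"], ["a", "b"])
        KD = compute_dominance_kinship(G)
        np.testing.assert_allclose(KD.values, [[0.25, 0.25], [0.25, 0.25]])

    def test_matches_bruteforce(self, rng):
        G = random_genotypes(rng, m=12, n=7, codes=(-1.0, -0.5, 0.0, 0.5, 1.0))
        KD = compute_dominance_kinship(G)
        W = 1.0 - np.abs(G.codes)
        expected = sum(np.outer(W[k], W[k]) for k in range(12)) / 12
        np.testing.assert_allclose(KD.values, expected, atol=1e-12)


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_kinship_is_psd_on_random_hybrid_panels(seed):
    r = np.random.default_rng(seed)
    G = random_genotypes(r, m=8, n=6, codes=(-1.0, -0.5, 0.0, 0.5, 1.0))
    assert compute_kinship(G).is_psd()
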