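"""Poset construction and average-rank estimators."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from marmot.errors import ConfigurationError, DataError, OracleInfeasibleError
from marmot.poset import (
    Poset,
    VariableSpec,
    assign_unit_ranks,
    average_rank_exact,
    average_rank_lpom0,
    average_rank_sampled,
    build_relation,
    check_transitivity,
    count_linear_extensions,
    encode_profiles,
    enumerate_linear_extensions,
    load_variable_specs,
)

from conftest import brute_force_average_rank, make_poset, random_poset


def chain(n):
    return make_poset([[i] for i in range(n)])


def antichain(n):
    """Pairwise-incomparable profiles via conflicting coordinates."""
    coords = np.zeros((n, n), dtype=int)
    coords[np.arange(n), np.arange(n)] = 1
    return make_poset(coords)


def v_poset():
    """a=(0,0) and b incomparable to a, both below c."""
    return make_poset([[1, 0], [0, 1], [1, 1]])


class TestEncoding:
    def test_deduplication_and_multiplicity(self):
        df = pd.DataFrame({"x": ["a", "a", "a"], "y": [1, 1, 1]})
        specs = [
            VariableSpec("x", "nominal", ("a", "b")),
            VariableSpec("y", "ordered", (0, 1)),
        ]
        poset, unit_map = encode_profiles(df, specs)
        assert poset.n_profiles == 1
        assert poset.multiplicity.tolist() == [3]
        assert unit_map.tolist() == [0, 0, 0]

    def test_ordered_index_coding_and_nominal_dummies(self):
        df = pd.DataFrame({"lvl": ["mid"], "cat": ["B"]})
        specs = [
            VariableSpec("lvl", "ordered", ("low", "mid", "high")),
            VariableSpec("cat", "nominal", ("A", "B", "C")),
        ]
        poset, _ = encode_profiles(df, specs)
        assert poset.coords.tolist() == [[1, 0, 1, 0]]

    def test_unknown_level_is_configuration_error(self):
        df = pd.DataFrame({"lvl": ["weird"]})
        specs = [VariableSpec("lvl", "ordered", ("low", "high"))]
        with pytest.raises(ConfigurationError, match="lvl"):
            encode_profiles(df, specs)

    def test_missing_value_is_data_error(self):
        df = pd.DataFrame({"lvl": ["low", None]})
        specs = [VariableSpec("lvl", "ordered", ("low", "high"))]
        with pytest.raises(DataError, match="row 1"):
            encode_profiles(df, specs)

    def test_spec_validation(self):
        with pytest.raises(ConfigurationError):
            VariableSpec("x", "ordered", ())
        with pytest.raises(ConfigurationError):
            VariableSpec("x", "nominal", ("a", "a"))
        with pytest.raises(ConfigurationError):
            VariableSpec("x", "fancy", ("a", "b"))

    def test_load_specs_from_mapping(self):
        specs = load_variable_specs(
            {"variables": [{"name": "x", "kind": "ordered", "levels": ["a", "b"]}]}
        )
        assert specs[0].n_coords == 1 and specs[0].levels == ("a", "b")


class TestRelation:
    @pytest.mark.parametrize(
        "a, b, expected_below",
        [([0, 0], [1, 1], True), ([0, 1], [1, 0], False)],
    )
    def test_dominance_pairs(self, a, b, expected_below):
        poset = make_poset([a, b])
        assert bool(poset.below[0, 1]) == expected_below
        assert not poset.below[1, 0]

    def test_single_ordered_variable_is_chain(self):
        poset = chain(5)
        assert poset.incomparabilities().sum() == 0
        assert count_linear_extensions(poset) == 1

    def test_relation_is_irreflexive_antisymmetric_transitive(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            poset = random_poset(rng, int(rng.integers(2, 15)))
            assert not poset.below.diagonal().any()
            assert not (poset.below & poset.below.T).any()
            assert check_transitivity(poset)


class TestLinearExtensions:
    def test_chain_has_one_extension(self):
        assert enumerate_linear_extensions(chain(3)) == [(0, 1, 2)]

    def test_antichain_has_factorial_extensions(self):
        exts = enumerate_linear_extensions(antichain(3))
        assert len(exts) == 6
        assert len(set(exts)) == 6

    def test_v_poset_extensions(self):
        exts = enumerate_linear_extensions(v_poset())
        assert sorted(exts) == [(0, 1, 2), (1, 0, 2)]

    def test_every_extension_is_a_topological_order(self):
        rng = np.random.default_rng(7)
        poset = random_poset(rng, 6)
        for ext in enumerate_linear_extensions(poset):
            pos = {e: i for i, e in enumerate(ext)}
            for i, j in np.argwhere(poset.below):
                assert pos[i] < pos[j]

    def test_cap_exceeded_raises(self):
        with pytest.raises(OracleInfeasibleError, match="cap"):
            enumerate_linear_extensions(antichain(6), cap=100)

    def test_count_matches_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            poset = random_poset(rng, 6)
            assert count_linear_extensions(poset) == len(
                enumerate_linear_extensions(poset)
            )


class TestExactAverageRank:
    def test_chain_positions(self):
        assert average_rank_exact(chain(3)).average_rank.tolist() == [1, 2, 3]

    def test_two_element_antichain(self):
        assert average_rank_exact(antichain(2)).average_rank.tolist() == [1.5, 1.5]

    def test_v_poset(self):
        ar = average_rank_exact(v_poset()).average_rank
        np.testing.assert_allclose(ar, [1.5, 1.5, 3.0])

    def test_matches_permutation_oracle_on_random_posets(self):
        rng = np.random.default_rng(5)
        for _ in range(15):
            poset = random_poset(rng, int(rng.integers(2, 7)))
            np.testing.assert_allclose(
                average_rank_exact(poset).average_rank,
                brute_force_average_rank(poset),
                atol=1e-12,
            )

    def test_order_preservation_and_sum_conservation(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            poset = random_poset(rng, 6)
            ar = average_rank_exact(poset).average_rank
            P = poset.n_profiles
            assert abs(ar.sum() - P * (P + 1) / 2) < 1e-9
            for i, j in np.argwhere(poset.below):
                assert ar[i] < ar[j]

    def test_dual_symmetry(self):
        rng = np.random.default_rng(13)
        poset = random_poset(rng, 6)
        dual = Poset(coords=poset.coords, multiplicity=poset.multiplicity,
                     below=poset.below.T.copy())
        ar = average_rank_exact(poset).average_rank
        ar_dual = average_rank_exact(dual).average_rank
        np.testing.assert_allclose(ar_dual, poset.n_profiles + 1 - ar, atol=1e-12)

    def test_normalized_rank_bounds(self):
        rt = average_rank_exact(antichain(4))
        assert np.all((rt.normalized_rank >= 0) & (rt.normalized_rank <= 1))
        single = make_poset([[0]])
        assert average_rank_exact(single).normalized_rank.tolist() == [0.0]


class TestLpom0:
    def test_chain_reduces_to_position(self):
        np.testing.assert_allclose(
            average_rank_lpom0(chain(4)).average_rank, [1, 2, 3, 4]
        )

    def test_v_poset_closed_form(self):
        ar = average_rank_lpom0(v_poset()).average_rank
        # top element: s=2, u=0 -> 3*4/4 = 3; legs: s=0, u=1 -> 1*4/3
        np.testing.assert_allclose(ar, [4 / 3, 4 / 3, 3.0])

    def test_antichain_closed_form(self):
        for P in (2, 4, 6):
            np.testing.assert_allclose(
                average_rank_lpom0(antichain(P)).average_rank, (P + 1) / 2
            )

    def test_bounded_error_vs_exact(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            poset = random_poset(rng, 7)
            exact = average_rank_exact(poset).average_rank
            approx = average_rank_lpom0(poset).average_rank
            assert np.abs(exact - approx).max() < poset.n_profiles / 2


class TestSampled:
    def test_chain_is_exact_for_any_sample_size(self):
        ar = average_rank_sampled(chain(4), n_samples=3, seed=0).average_rank
        np.testing.assert_allclose(ar, [1, 2, 3, 4])

    def test_two_element_antichain_converges(self):
        ar = average_rank_sampled(antichain(2), n_samples=4000, seed=1).average_rank
        np.testing.assert_allclose(ar, [1.5, 1.5], atol=0.05)

    def test_v_poset_large_sample(self):
        ar = average_rank_sampled(v_poset(), n_samples=10_000, seed=2).average_rank
        assert ar[2] == 3.0
        assert abs(ar[0] - 1.5) < 0.05

    def test_reproducible_under_seed(self):
        poset = random_poset(np.random.default_rng(19), 6)
        a = average_rank_sampled(poset, 500, seed=7).average_rank
        b = average_rank_sampled(poset, 500, seed=7).average_rank
        np.testing.assert_array_equal(a, b)

    def test_counting_sampler_path_agrees_with_exact(self):
        # force the sequential counting sampler by shrinking the enumeration limit
        poset = random_poset(np.random.default_rng(23), 7)
        exact = average_rank_exact(poset).average_rank
        ar = average_rank_sampled(
            poset, n_samples=4000, seed=3, enumerate_limit=1
        ).average_rank
        assert np.abs(ar - exact).max() < 0.15

    def test_topo_sampler_path_runs_on_large_poset(self):
        rng = np.random.default_rng(29)
        poset = random_poset(rng, 25, n_coords=4)
        ar = average_rank_sampled(poset, n_samples=200, seed=4).average_rank
        assert ar.shape == (25,)
        assert np.all((ar >= 1) & (ar <= 25))


class TestUnitRanks:
    def test_units_share_profile_rank(self):
        df = pd.DataFrame({"x": ["a", "a", "a"]})
        specs = [VariableSpec("x", "ordered", ("a", "b"))]
        poset, unit_map = encode_profiles(df, specs)
        build_relation(poset)
        rt = average_rank_exact(poset)
        ars = assign_unit_ranks(rt, unit_map)
        assert len(ars) == 3 and len(set(ars)) == 1

    def test_monotone_on_chain_data(self):
        df = pd.DataFrame({"x": ["low", "high", "mid", "low"]})
        specs = [VariableSpec("x", "ordered", ("low", "mid", "high"))]
        poset, unit_map = encode_profiles(df, specs)
        build_relation(poset)
        ars = assign_unit_ranks(average_rank_exact(poset), unit_map)
        assert ars[0] < ars[2] < ars[1] and ars[0] == ars[3]

    def test_distinct_values_bounded_by_profiles(self):
        rng = np.random.default_rng(31)
        df = pd.DataFrame({"x": rng.choice(["a", "b", "c"], 50),
                           "y": rng.choice(["u", "v"], 50)})
        specs = [VariableSpec("x", "ordered", ("a", "b", "c")),
                 VariableSpec("y", "ordered", ("u", "v"))]
        poset, unit_map = encode_profiles(df, specs)
        build_relation(poset)
        ars = assign_unit_ranks(average_rank_lpom0(poset), unit_map)
        assert len(np.unique(ars)) <= poset.n_profiles <= 50


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.lists(st.tuples(st.integers(0, 2), st.integers(0, 2)),
                min_size=2, max_size=6, unique=True))
def test_exact_ar_properties_hypothesis(coord_rows):
    """Sum conservation and strict order preservation on arbitrary small posets."""
    poset = make_poset(list(coord_rows))
    ar = average_rank_exact(poset).average_rank
    P = poset.n_profiles
    assert abs(ar.sum() - P * (P + 1) / 2) < 1e-9
    for i, j in np.argwhere(poset.below):
        assert ar[i] < ar[j]
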