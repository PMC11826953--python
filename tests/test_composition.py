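"""Aitchison-geometry primitives: transforms, statistics, reallocations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import dietsleep as ds
from dietsleep.composition import InfeasibleReallocationError, ReallocationSpec

from conftest import random_compositions

positive_grams = st.lists(
    st.floats(min_value=0.5, max_value=500.0, allow_nan=False), min_size=5, max_size=5
)


class TestEnergyShares:
    def test_hand_example(self):
        shares = ds.energy_shares([80, 250, 20, 25, 15])
        # kcal (320, 1000, 180, 225, 135), total 1860
        np.testing.assert_allclose(
            shares, [0.1720, 0.5376, 0.0968, 0.1210, 0.0726], atol=5e-5
        )
        assert abs(shares.sum() - 1.0) < 1e-12

    def test_equal_energies_give_uniform(self):
        # 4 kcal/g * 90 g == 9 kcal/g * 40 g
        np.testing.assert_allclose(ds.energy_shares([90, 90, 40, 40, 40]), np.full(5, 0.2))

    @pytest.mark.parametrize("grams", [[0, 1, 1, 1, 1], [1, 1, -2, 1, 1]])
    def test_nonpositive_gram_rejected(self, grams):
        with pytest.raises(ValueError):
            ds.energy_shares(grams)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(positive_grams)
    def test_closure_property(self, grams):
        shares = ds.energy_shares(grams)
        assert abs(shares.sum() - 1.0) < 1e-9
        assert np.all(shares > 0)


class TestClosure:
    def test_examples(self):
        np.testing.assert_allclose(ds.closure([2, 3, 5]), [0.2, 0.3, 0.5])
        np.testing.assert_allclose(ds.closure([1, 1, 1, 1, 1]), np.full(5, 0.2))

    def test_idempotent_and_scale_invariant(self):
        rng = np.random.default_rng(0)
        v = rng.lognormal(size=5)
        c = ds.closure(v)
        np.testing.assert_allclose(ds.closure(c), c)
        np.testing.assert_allclose(ds.closure(3.7 * v), c)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            ds.closure([1.0, 0.0, 2.0])


class TestLogRatioTransforms:
    def test_alr_hand_example(self):
        z = ds.alr([0.4, 0.2, 0.2, 0.1, 0.1])
        np.testing.assert_allclose(z, [np.log(4), np.log(2), np.log(2), 0.0], atol=1e-12)

    def test_uniform_maps_to_zero(self):
        u = np.full(5, 0.2)
        np.testing.assert_allclose(ds.alr(u), 0.0, atol=1e-12)
        for focal in ("default", *ds.NUTRIENTS):
            np.testing.assert_allclose(ds.ilr(u, ds.make_basis(5, focal)), 0.0, atol=1e-12)

    def test_round_trips_bulk(self):
        rng = np.random.default_rng(11)
        comps = random_compositions(rng, 1000)
        np.testing.assert_allclose(ds.alr_inv(ds.alr(comps)), comps, atol=1e-10)
        for focal in ("default", "protein", "polyunsaturated_fat"):
            B = ds.make_basis(5, focal)
            np.testing.assert_allclose(ds.ilr_inv(ds.ilr(comps, B), B), comps, atol=1e-10)

    def test_isometry_across_bases(self):
        rng = np.random.default_rng(5)
        x, y = random_compositions(rng, 2)
        dists = [
            np.linalg.norm(ds.ilr(x, ds.make_basis(5, f)) - ds.ilr(y, ds.make_basis(5, f)))
            for f in ("default", *ds.NUTRIENTS)
        ]
        np.testing.assert_allclose(dists, dists[0], atol=1e-12)

    def test_cross_check_against_scikit_bio(self):
        from skbio.stats import composition as skb

        rng = np.random.default_rng(3)
        comps = random_compositions(rng, 20)
        np.testing.assert_allclose(ds.closure(comps * 7.0), skb.closure(comps * 7.0), atol=1e-12)
        # skbio's alr uses a configurable reference part; ours is the last
        np.testing.assert_allclose(
            ds.alr(comps), skb.alr(comps, ref_idx=comps.shape[1] - 1), atol=1e-10
        )
        # ilr coordinates are basis-dependent but distances are not
        ours = ds.ilr(comps)
        theirs = skb.ilr(comps)
        d_ours = np.linalg.norm(ours[:, None, :] - ours[None, :, :], axis=-1)
        d_theirs = np.linalg.norm(theirs[:, None, :] - theirs[None, :, :], axis=-1)
        np.testing.assert_allclose(d_ours, d_theirs, atol=1e-8)


class TestBasis:
    def test_two_part_basis(self):
        B = ds.make_basis(2)
        np.testing.assert_allclose(np.abs(B), [[np.sqrt(0.5), np.sqrt(0.5)]], atol=1e-12)

    @pytest.mark.parametrize("focal", ["default", *ds.NUTRIENTS])
    def test_orthonormal_rows_sum_zero(self, focal):
        B = ds.make_basis(5, focal)
        np.testing.assert_allclose(B @ B.T, np.eye(4), atol=1e-10)
        np.testing.assert_allclose(B.sum(axis=1), 0.0, atol=1e-12)

    def test_protein_pivot_first_balance(self):
        x = np.array([0.18, 0.54, 0.10, 0.12, 0.06])
        z1 = ds.ilr(x, ds.make_basis(5, "protein"))[0]
        # direct evaluation of the pivot formula as oracle
        expected = np.sqrt(4 / 5) * np.log(x[0] / np.exp(np.mean(np.log(x[1:]))))
        assert abs(z1 - expected) < 1e-12
        assert abs(z1 - 0.2221) < 5e-4

    def test_invalid_focal(self):
        with pytest.raises(ValueError):
            ds.make_basis(5, "fibre")


class TestVariationMatrix:
    def test_proportional_parts_have_zero_entry(self):
        rng = np.random.default_rng(1)
        base = rng.lognormal(size=(30, 4))
        data = ds.closure(np.column_stack([2 * base[:, 0], base]))
        T = ds.variation_matrix(data)
        assert abs(T[0, 1]) < 1e-12
        np.testing.assert_allclose(np.diag(T), 0.0, atol=1e-12)
        np.testing.assert_allclose(T, T.T, atol=1e-12)

    def test_brute_force_oracle(self):
        data = ds.closure(np.array([[1, 2, 3, 4, 5], [2, 2, 2, 5, 9], [7, 1, 3, 3, 6.0]]))
        T = ds.variation_matrix(data)
        for i in range(5):
            for j in range(5):
                expected = np.var(np.log(data[:, i] / data[:, j]), ddof=1)
                assert abs(T[i, j] - expected) < 1e-12

    def test_needs_two_samples(self):
        with pytest.raises(ValueError):
            ds.variation_matrix(np.full((1, 5), 0.2))


class TestCompositionalMean:
    def test_identical_rows(self):
        x = ds.closure([1, 2, 3, 4, 5.0])
        np.testing.assert_allclose(ds.compositional_mean(np.tile(x, (4, 1))), x, atol=1e-12)

    def test_dual_route_two_rows(self):
        rng = np.random.default_rng(2)
        data = random_compositions(rng, 2)
        geometric = ds.closure(np.sqrt(data[0] * data[1]))
        via_ilr = ds.ilr_inv(ds.ilr(data).mean(axis=0))
        np.testing.assert_allclose(ds.compositional_mean(data), geometric, atol=1e-12)
        np.testing.assert_allclose(ds.compositional_mean(data), via_ilr, atol=1e-12)

    def test_permutation_invariance_and_equivariance(self):
        rng = np.random.default_rng(4)
        data = random_compositions(rng, 9)
        m = ds.compositional_mean(data)
        np.testing.assert_allclose(ds.compositional_mean(data[::-1]), m, atol=1e-14)
        p = ds.closure([3, 1, 1, 2, 1.0])
        perturbed = np.vstack([ds.perturb(row, p) for row in data])
        np.testing.assert_allclose(
            ds.compositional_mean(perturbed), ds.perturb(m, p), atol=1e-12
        )


class TestReallocate:
    x = np.array([0.18, 0.54, 0.10, 0.12, 0.06])

    def test_add_hand_example(self):
        out = ds.reallocate(self.x, ReallocationSpec("protein", 0.06, "add"))
        np.testing.assert_allclose(out, [0.24, 0.50049, 0.09268, 0.11122, 0.05561], atol=5e-5)

    def test_take_hand_example(self):
        out = ds.reallocate(self.x, ReallocationSpec("protein", 0.06, "take"))
        np.testing.assert_allclose(out, [0.12, 0.57951, 0.10732, 0.12878, 0.06439], atol=5e-5)

    def test_zero_delta_identity(self):
        np.testing.assert_allclose(
            ds.reallocate(self.x, ReallocationSpec("carbohydrate", 0.0, "add")), self.x
        )

    def test_output_closed_and_positive(self):
        for nutrient in ds.NUTRIENTS:
            for mode in ("take", "add"):
                out = ds.reallocate(self.x, ReallocationSpec(nutrient, 0.05, mode))
                assert abs(out.sum() - 1.0) < 1e-9 and np.all(out > 0)

    def test_infeasible_delta_names_cap(self):
        # taking more than the smallest share drains it to zero
        with pytest.raises(InfeasibleReallocationError, match="cap"):
            ds.reallocate(self.x, ReallocationSpec("polyunsaturated_fat", 0.07, "take"))

    def test_take_undoes_add_exactly(self):
        # proportional redistribution makes add and take mutual inverses
        spec_a = ReallocationSpec("protein", 0.05, "add")
        spec_t = ReallocationSpec("protein", 0.05, "take")
        round_trip = ds.reallocate(ds.reallocate(self.x, spec_a), spec_t)
        np.testing.assert_allclose(round_trip, self.x, atol=1e-12)


class TestSubstitutePairwise:
    def test_hand_example(self):
        x = np.array([0.18, 0.54, 0.10, 0.115, 0.065])
        out = ds.substitute_pairwise(x, "polyunsaturated_fat", "protein", 0.06)
        np.testing.assert_allclose(out, [0.24, 0.54, 0.10, 0.115, 0.005], atol=1e-12)
        # untouched parts are bit-identical and the sum is preserved exactly
        assert out[1] == x[1] and out[2] == x[2] and out[3] == x[3]
        assert out.sum() == x.sum()

    def test_identities(self):
        x = ds.closure([1, 2, 3, 4, 5.0])
        np.testing.assert_allclose(ds.substitute_pairwise(x, "protein", "carb", 0.0), x)
        np.testing.assert_allclose(ds.substitute_pairwise(x, "carb", "carb", 0.04), x)

    def test_infeasible(self):
        x = np.array([0.18, 0.54, 0.10, 0.115, 0.065])
        with pytest.raises(InfeasibleReallocationError):
            ds.substitute_pairwise(x, "polyunsaturated_fat", "protein", 0.07)
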