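import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import treefuse as tf
from treefuse.fusion import FusionParams


def random_instance(rng, max_d=4, max_R=3):
    dims = [int(rng.integers(1, max_d + 1)) for _ in range(3)]
    R = int(rng.integers(1, max_R + 1))
    zs = [rng.standard_normal(d + 1) for d in dims]
    for z in zs:
        z[-1] = 1.0  # augmented convention
    params = FusionParams(
        lam=rng.standard_normal(R),
        projections=[rng.standard_normal((R, d + 1)) for d in dims],
    )
    return zs, params


class TestAugment:
    def test_appends_trailing_ones(self):
        out = tf.augment(np.array([[2.0, 3.0]]))
        np.testing.assert_array_equal(out, [[2.0, 3.0, 1.0]])

    def test_empty_embedding(self):
        out = tf.augment(np.zeros((3, 0)))
        np.testing.assert_array_equal(out, np.ones((3, 1)))

    def test_double_augment_two_ones(self):
        out = tf.augment(tf.augment(np.array([[5.0]])))
        np.testing.assert_array_equal(out, [[5.0, 1.0, 1.0]])


class TestFullTensor:
    def test_scalar_case(self):
        np.testing.assert_array_equal(
            tf.full_tensor([1.0], [1.0], [1.0]), [[[1.0]]])

    def test_outer_product_slice(self):
        T = tf.full_tensor([2.0, 1.0], [3.0, 1.0], [1.0])
        np.testing.assert_array_equal(T[:, :, 0], [[6.0, 2.0], [3.0, 1.0]])

    def test_sub_blocks_recover_lower_order_terms(self, rng):
        # with trailing 1s, fixing the 1-index of other modalities
        # recovers unimodal / bimodal products
        z1, z2, z3 = (tf.augment(rng.standard_normal((1, 3)))[0]
                      for _ in range(3))
        T = tf.full_tensor(z1, z2, z3)
        d1, d2, d3 = len(z1) - 1, len(z2) - 1, len(z3) - 1
        np.testing.assert_allclose(T[:, d2, d3], z1)          # unimodal
        np.testing.assert_allclose(T[:, :, d3], np.outer(z1, z2))  # bimodal
        assert T[0, 1, d3] == pytest.approx(z1[0] * z2[1])

    def test_cap_enforced(self):
        big = np.ones(200)
        with pytest.raises(ValueError, match="low-rank"):
            tf.full_tensor(big, big, big)


class TestLowRankFuse:
    def test_trivial_rank_one(self):
        params = FusionParams(lam=[1.0], projections=[np.ones((1, 1))] * 3)
        np.testing.assert_allclose(
            tf.lowrank_fuse([1.0], [1.0], [1.0], params), [1.0])

    def test_hand_example(self):
        # P_i chosen so P_i z_i give the stated projected vectors
        params = FusionParams(
            lam=[1.0, 0.5],
            projections=[np.array([[2.0], [1.0]]), np.array([[3.0], [-1.0]]),
                         np.array([[1.0], [2.0]])],
        )
        h = tf.lowrank_fuse([1.0], [1.0], [1.0], params)
        np.testing.assert_allclose(h, [6.0, -1.0])

    def test_equals_full_tensor_contraction(self, rng):
        # core oracle property over many random small instances
        for _ in range(120):
            zs, params = random_instance(rng)
            h = tf.lowrank_fuse(*zs, params)
            T = tf.full_tensor(*zs)
            for r in range(params.rank):
                expected = params.lam[r] * np.einsum(
                    "abc,a,b,c->", T, params.projections[0][r],
                    params.projections[1][r], params.projections[2][r])
                assert h[r] == pytest.approx(expected, abs=1e-8)

    def test_batched_matches_per_sample(self, rng):
        zs, params = random_instance(rng)
        batch = [np.vstack([z, 2 * z]) for z in zs]
        H = tf.lowrank_fuse(*batch, params)
        np.testing.assert_allclose(H[0], tf.lowrank_fuse(*zs, params))

    def test_scale_bilinearity(self, rng):
        zs, params = random_instance(rng)
        h = tf.lowrank_fuse(*zs, params)
        h_scaled = tf.lowrank_fuse(3.0 * zs[0], zs[1], zs[2], params)
        np.testing.assert_allclose(h_scaled, 3.0 * h, atol=1e-10)

    def test_zero_projection_propagates(self, rng):
        zs, params = random_instance(rng)
        params.projections[1][:] = 0.0
        np.testing.assert_array_equal(tf.lowrank_fuse(*zs, params),
                                      np.zeros(params.rank))


class TestCPReconstruct:
    def test_all_ones(self):
        params = FusionParams(lam=[1.0], projections=[np.ones((1, 2))] * 3)
        np.testing.assert_array_equal(tf.cp_reconstruct(params),
                                      np.ones((2, 2, 2)))

    def test_rank_one_exact(self, rng):
        u, v, w = rng.standard_normal(3), rng.standard_normal(2), \
            rng.standard_normal(4)
        params = FusionParams(lam=[1.0],
                              projections=[u[None], v[None], w[None]])
        np.testing.assert_allclose(tf.cp_reconstruct(params),
                                   np.einsum("a,b,c->abc", u, v, w))

    def test_contraction_identity(self, rng):
        for _ in range(30):
            zs, params = random_instance(rng)
            W = tf.cp_reconstruct(params)
            total = np.einsum("abc,a,b,c->", W, *zs)
            assert total == pytest.approx(
                tf.lowrank_fuse(*zs, params).sum(), abs=1e-8)


class TestMaxRankBound:
    @pytest.mark.parametrize("dims,expected",
                             [((2, 2, 2), 4), ((3, 4, 5), 12), ((1, 1, 1), 1)])
    def test_bound(self, dims, expected):
        assert tf.max_rank_bound(*dims) == expected

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            tf.max_rank_bound(0, 2, 2)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1))
def test_lowrank_full_equivalence_property(seed):
    """Low-rank fusion equals the explicit tensor contraction."""
    rng = np.random.default_rng(seed)
    zs, params = random_instance(rng)
    h = tf.lowrank_fuse(*zs, params)
    W = tf.cp_reconstruct(params)
    T = tf.full_tensor(*zs)
    np.testing.assert_allclose(h.sum(), np.sum(W * T), atol=1e-8)
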