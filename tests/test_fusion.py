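"""Selective Fusion Module: Euclidean gate, blockwise similarity, fusion."""

import inspect

import numpy as np
import pytest

from m3bnet.fusion import block_similarity, euclidean_distance, select_and_fuse
from m3bnet.nn import Tensor


class TestEuclideanDistance:
    def test_identity_is_zero(self, rng):
        x = rng.random(17)
        assert euclidean_distance(x, x) == 0.0

    def test_three_four_five(self):
        assert euclidean_distance((0.0, 3.0), (4.0, 0.0)) == pytest.approx(5.0)

    def test_symmetry_on_random_vectors(self, rng):
        for _ in range(20):
            x, y = rng.random(9), rng.random(9)
            assert euclidean_distance(x, y) == euclidean_distance(y, x)

    def test_matches_direct_arithmetic(self, rng):
        for _ in range(50):
            x, y = rng.random(12), rng.random(12)
            expected = np.sqrt(((x - y) ** 2).sum())
            assert euclidean_distance(x, y) == pytest.approx(expected, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            euclidean_distance([1, 2], [1, 2, 3])


class TestBlockSimilarity:
    def test_identical_maps_fully_similar(self, rng):
        z = rng.random((3, 8, 8))
        rep = block_similarity(z, z, grid=(2, 2))
        np.testing.assert_allclose(rep.similarities, 1.0)
        assert rep.fused_flags.all()

    def test_binary_complement_is_maximally_distant(self):
        z1 = (np.indices((8, 8)).sum(axis=0) % 2).astype(float)
        rep = block_similarity(z1, 1.0 - z1, grid=(2, 2))
        np.testing.assert_allclose(rep.similarities, 0.0, atol=1e-12)
        np.testing.assert_allclose(rep.distances, np.sqrt(16.0))
        assert not rep.fused_flags.any()

    def test_hand_built_grid_matches_per_block_oracle(self, rng):
        a, b = rng.random((4, 4)), rng.random((4, 4))
        rep = block_similarity(a, b, grid=(2, 2))
        lo = min(a.min(), b.min())
        hi = max(a.max(), b.max())
        an, bn = (a - lo) / (hi - lo), (b - lo) / (hi - lo)
        for i in range(2):
            for j in range(2):
                xa = an[2 * i:2 * i + 2, 2 * j:2 * j + 2].ravel()
                xb = bn[2 * i:2 * i + 2, 2 * j:2 * j + 2].ravel()
                d = np.sqrt(((xa - xb) ** 2).sum())
                assert rep.distances[i, j] == pytest.approx(d, abs=1e-12)
                assert rep.similarities[i, j] == pytest.approx(1 - d / 2.0, abs=1e-12)

    def test_similarity_bounded_in_unit_interval(self, rng):
        for _ in range(10):
            rep = block_similarity(rng.random((2, 8, 8)), rng.random((2, 8, 8)))
            assert (rep.similarities >= 0).all() and (rep.similarities <= 1).all()

    def test_non_dividing_grid_truncates_edge_blocks(self, rng):
        rep = block_similarity(rng.random((7, 7)), rng.random((7, 7)), grid=(2, 2))
        assert rep.distances.shape == (2, 2)


class TestSelectAndFuse:
    def test_default_threshold_is_half(self):
        sig = inspect.signature(select_and_fuse)
        assert sig.parameters["threshold"].default == 0.5

    def test_idempotent_on_identical_inputs(self, rng):
        z = rng.random((3, 8, 8)).astype(np.float32)
        fused = select_and_fuse(z, z.copy())
        np.testing.assert_array_equal(fused.tensor, z)

    def test_single_flagged_block_changes_only_that_block(self, rng):
        # z2 equals z1 except inside the top-left block where it is the
        # (jointly normalized) complement: exactly that block stays unfused
        z1 = (np.indices((8, 8)).sum(axis=0) % 2).astype(np.float32)
        z2 = z1.copy()
        z2[:4, :4] = 1.0 - z1[:4, :4]
        fused = select_and_fuse(z1, z2, grid=(2, 2))
        rep = fused.provenance
        assert rep.fused_flags.sum() == 3 and not rep.fused_flags[0, 0]
        np.testing.assert_array_equal(fused.tensor[:4, :4], z1[:4, :4])
        np.testing.assert_allclose(fused.tensor[4:, 4:], 0.5 * (z1 + z2)[4:, 4:])

    def test_threshold_monotonicity_over_sweep(self, rng):
        z1, z2 = rng.random((2, 16, 16)), rng.random((2, 16, 16))
        counts = [select_and_fuse(z1, z2, threshold=t).provenance.n_fused
                  for t in np.linspace(0.0, 1.0, 11)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        assert counts[0] == 16  # threshold 0 fuses everything

    def test_locality_of_z2_perturbation(self, rng):
        z1 = rng.random((2, 8, 8))
        z2 = rng.random((2, 8, 8))
        z2b = z2.copy()
        z2b[:, :4, :4] += 0.05  # stays within a single (2,2)-grid block
        a = select_and_fuse(z1, z2, grid=(2, 2)).tensor
        b = select_and_fuse(z1, z2b, grid=(2, 2)).tensor
        outside = np.ones((8, 8), dtype=bool)
        outside[:4, :4] = False
        np.testing.assert_array_equal(a[:, outside], b[:, outside])

    def test_missing_z2_passes_z1_through(self, rng):
        z1 = rng.random((2, 8, 8))
        fused = select_and_fuse(z1, None)
        assert fused.tensor is z1 and fused.provenance is None

    def test_bad_threshold_rejected(self, rng):
        with pytest.raises(ValueError):
            select_and_fuse(rng.random((2, 4, 4)), rng.random((2, 4, 4)), threshold=1.5)

    def test_batched_tensor_path_matches_single_sample(self, rng):
        z1 = rng.random((2, 3, 8, 8)).astype(np.float32)
        z2 = rng.random((2, 3, 8, 8)).astype(np.float32)
        batched = select_and_fuse(Tensor(z1), Tensor(z2))
        for i in range(2):
            single = select_and_fuse(z1[i], z2[i])
            np.testing.assert_allclose(batched.tensor.data[i], single.tensor, atol=1e-6)

    def test_sampled_mode_is_seeded_and_off_mode_bypasses(self, rng):
        z1 = rng.random((2, 8, 8))
        z2 = rng.random((2, 8, 8))
        a = select_and_fuse(z1, z2, mode="sampled", rng_seed=3)
        b = select_and_fuse(z1, z2, mode="sampled", rng_seed=3)
        np.testing.assert_array_equal(a.tensor, b.tensor)
        off = select_and_fuse(z1, z2, mode="off")
        assert off.tensor is z1

    def test_sum_operator_adds_on_fused_blocks(self, rng):
        z = rng.random((2, 8, 8)).astype(np.float32)
        fused = select_and_fuse(z, z.copy(), op="sum")
        np.testing.assert_allclose(fused.tensor, 2.0 * z, atol=1e-7)
        with pytest.raises(ValueError):
            select_and_fuse(z, z, op="max")

    def test_report_serializes_to_json(self, rng):
        import json
        rep = select_and_fuse(rng.random((2, 8, 8)), rng.random((2, 8, 8))).provenance
        parsed = json.loads(rep.to_json())
        assert parsed["block_grid"] == [4, 4] and parsed["threshold"] == 0.5
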