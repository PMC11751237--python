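"""Vascular phantom generator: tree geometry, rasterization, rendering, I/O."""

import dataclasses
import hashlib

import numpy as np
import pytest

from m3bnet.phantom import (PhantomParams, VesselTree, generate_dataset, generate_pair,
                            generate_vessel_tree, load_dataset, rasterize_tree, render_pair)


class TestVesselTree:
    def test_depth_one_single_tree_is_one_unbranched_segment(self):
        params = PhantomParams(depth=1, n_trees=1)
        tree = generate_vessel_tree(params, rng_seed=0)
        assert len(tree.segments) == 1
        assert len(tree.roots) == 1

    def test_same_seed_reproduces_identical_segments(self, default_params):
        t1 = generate_vessel_tree(default_params, rng_seed=5)
        t2 = generate_vessel_tree(default_params, rng_seed=5)
        assert t1.segments == t2.segments

    def test_terminal_widths_follow_closed_form_decay(self):
        # width at generation g is width_root * decay**g; depth 4 => 8*0.7^3
        params = PhantomParams(depth=4, width_decay=0.7, width_root=8.0, n_trees=1)
        tree = generate_vessel_tree(params, rng_seed=3)
        widths = sorted({round(w, 6) for _, _, w in tree.segments})
        expected = sorted(round(8.0 * 0.7 ** g, 6) for g in range(4))
        assert widths == expected
        assert min(widths) == pytest.approx(8.0 * 0.7 ** 3)

    def test_children_start_where_parent_ends_and_widths_never_grow(self, default_params):
        tree = generate_vessel_tree(default_params, rng_seed=11)
        endpoints = {seg[1] for seg in tree.segments}
        starts = {seg[0] for seg in tree.segments}
        # every non-root start is some parent's end
        non_root_starts = starts - set(tree.roots)
        assert non_root_starts <= endpoints
        c = default_params.canvas_size
        for (r0, c0), (r1, c1), w in tree.segments:
            assert w > 0
            for v in (r0, c0, r1, c1):
                assert 0 <= v <= c - 1

    @pytest.mark.parametrize("field,value", [
        ("canvas_size", 32), ("depth", 0), ("width_decay", 0.0),
        ("uwf_contrast", 0.9), ("noise_sigma", 2.0),
    ])
    def test_invalid_params_raise_naming_the_field(self, field, value):
        params = dataclasses.replace(PhantomParams(), **{field: value})
        with pytest.raises(ValueError) as err:
            params.validate()
        token = field if field not in ("uwf_contrast",) else "uwf_contrast"
        assert token in str(err.value)


class TestRasterize:
    def test_horizontal_segment_paints_exact_band(self):
        # width-3 butt-capped line from (10,32) to (54,32): rows 31..33, cols 10..54
        tree = VesselTree(segments=[((32.0, 10.0), (32.0, 54.0), 3.0)], roots=[(32.0, 10.0)], depth=1)
        mask = rasterize_tree(tree, 64)
        expected = np.zeros((64, 64), dtype=np.uint8)
        expected[31:34, 10:55] = 1
        np.testing.assert_array_equal(mask, expected)

    def test_empty_tree_rasterizes_to_zero_mask(self):
        mask = rasterize_tree(VesselTree(segments=[], roots=[], depth=1), 64)
        assert mask.sum() == 0

    def test_disjoint_segments_union_area(self):
        seg_a = ((10.0, 5.0), (10.0, 25.0), 2.0)
        seg_b = ((50.0, 5.0), (50.0, 25.0), 2.0)
        both = rasterize_tree(VesselTree([seg_a, seg_b], [], 1), 64)
        only_a = rasterize_tree(VesselTree([seg_a], [], 1), 64)
        only_b = rasterize_tree(VesselTree([seg_b], [], 1), 64)
        np.testing.assert_array_equal(both, np.maximum(only_a, only_b))
        assert both.sum() == only_a.sum() + only_b.sum()

    def test_matches_brute_force_distance_oracle_on_oblique_segment(self):
        seg = ((12.3, 7.9), (51.2, 44.6), 3.4)
        mask = rasterize_tree(VesselTree([seg], [], 1), 64)
        (r0, c0), (r1, c1), w = seg
        length = np.hypot(r1 - r0, c1 - c0)
        ur, uc = (r1 - r0) / length, (c1 - c0) / length
        oracle = np.zeros((64, 64), dtype=np.uint8)
        for r in range(64):
            for c in range(64):
                t = (r - r0) * ur + (c - c0) * uc
                perp = abs((r - r0) * uc - (c - c0) * ur)
                if 0 <= t <= length and perp <= w / 2:
                    oracle[r, c] = 1
        np.testing.assert_array_equal(mask, oracle)


class TestRender:
    def test_noiseless_even_render_takes_exactly_two_values(self, clean_pair):
        values = np.unique(clean_pair.uwf)
        assert len(values) == 2
        ffa_values = np.unique(clean_pair.ffa)
        assert len(ffa_values) == 2

    def test_contrast_directions_over_many_seeds(self, default_params):
        # UWF: vessels darker than background; FFA: vessels brighter; FFA gap larger
        for seed in range(20):
            pair = generate_pair(default_params, seed)
            on, off = pair.mask == 1, pair.mask == 0
            uwf_gap = pair.uwf[off].mean() - pair.uwf[on].mean()
            ffa_gap = pair.ffa[on].mean() - pair.ffa[off].mean()
            assert uwf_gap > 0
            assert ffa_gap > 0
            assert ffa_gap > uwf_gap

    def test_render_is_bit_deterministic(self, default_params, clean_pair):
        a = render_pair(clean_pair.mask, default_params, 99)
        b = render_pair(clean_pair.mask, default_params, 99)
        np.testing.assert_array_equal(a.uwf, b.uwf)
        np.testing.assert_array_equal(a.ffa, b.ffa)

    def test_pair_arrays_share_shape_and_mask_is_binary(self, sample_pair):
        assert sample_pair.uwf.shape == sample_pair.ffa.shape == sample_pair.mask.shape
        assert set(np.unique(sample_pair.mask)) <= {0, 1}
        assert sample_pair.valid_mask is not None

    def test_non_binary_mask_rejected(self, default_params):
        with pytest.raises(ValueError):
            render_pair(np.full((64, 64), 0.5), default_params, 0)


class TestDataset:
    def test_manifest_row_count_matches_dataset_size(self, tmp_path, default_params):
        manifest = generate_dataset(120, dataclasses.replace(default_params, canvas_size=64),
                                    tmp_path, seed=1)
        rows = manifest.read_text().strip().splitlines()
        assert len(rows) == 121  # header + 120 pairs

    def test_empty_dataset_writes_empty_manifest(self, tmp_path, default_params):
        manifest = generate_dataset(0, default_params, tmp_path, seed=1)
        assert manifest.read_text().strip().splitlines()[0].startswith("id,")
        assert len(list(tmp_path.glob("*.png"))) == 0

    def test_regeneration_is_byte_identical(self, tmp_path, default_params):
        params = dataclasses.replace(default_params, canvas_size=64)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate_dataset(3, params, d1, seed=9)
        generate_dataset(3, params, d2, seed=9)
        for p1 in sorted(d1.glob("*.png")):
            h1 = hashlib.sha256(p1.read_bytes()).hexdigest()
            h2 = hashlib.sha256((d2 / p1.name).read_bytes()).hexdigest()
            assert h1 == h2, p1.name

    def test_roundtrip_within_8bit_quantization(self, tmp_path, default_params):
        params = dataclasses.replace(default_params, canvas_size=64)
        manifest = generate_dataset(2, params, tmp_path, seed=4)
        loaded = load_dataset(manifest)
        assert len(loaded) == 2
        regenerated = generate_pair(params, loaded[0].meta["seed"])
        assert np.abs(loaded[0].uwf - regenerated.uwf).max() <= 1.0 / 255.0 + 1e-6
        np.testing.assert_array_equal(loaded[0].mask, regenerated.mask)
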