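"""HOG pseudo-label extraction against brute-force per-pixel oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hogseg.hog import (
    HOGConfig,
    HOGConfigError,
    batch_extract,
    block_normalize,
    cell_histograms,
    compute_gradients,
    descriptor_length,
    hog_descriptor,
    read_store_config,
    read_store_vectors,
    to_grayscale,
)
from hogseg.synthetic import SceneConfig, generate_scene

from .oracle import cell_histograms_loops, gradients_loops, hog_descriptor_loops


class TestGradients:
    def test_constant_image_has_zero_gradient(self):
        g = compute_gradients(np.full((10, 12), 7.0))
        assert np.all(g.gx == 0) and np.all(g.gy == 0)
        assert np.all(g.magnitude == 0) and np.all(g.orientation == 0)

    def test_horizontal_ramp(self):
        img = np.tile(np.arange(8.0), (6, 1))
        g = compute_gradients(img)
        interior = g.gx[:, 1:-1]
        assert np.all(interior == 2.0)
        assert np.all(g.gy == 0)
        assert np.all(g.magnitude[:, 1:-1] == 2.0)
        assert np.all(g.orientation == 0.0)

    def test_matches_double_loop_oracle(self, rng):
        img = rng.integers(0, 256, size=(5, 5)).astype(np.float64)
        g = compute_gradients(img)
        gx, gy, mag, ori = gradients_loops(img)
        np.testing.assert_allclose(g.gx, gx)
        np.testing.assert_allclose(g.gy, gy)
        np.testing.assert_allclose(g.magnitude, mag)
        np.testing.assert_allclose(g.orientation, ori)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError, match="2-D"):
            compute_gradients(np.zeros((3, 3, 3)))
        with pytest.raises(ValueError, match="empty"):
            compute_gradients(np.zeros((0, 4)))


class TestCellHistograms:
    def test_zero_field_gives_zero_histograms(self):
        g = compute_gradients(np.zeros((32, 32)))
        out = cell_histograms(g, HOGConfig(resize_width=32, resize_height=32))
        assert out.hist.shape == (2, 2, 6)
        assert np.all(out.hist == 0)

    def test_single_pixel_nearest_bin_vote(self):
        # one pixel at 45 degrees with magnitude 2 lands whole in bin 1 of 6
        g = compute_gradients(np.zeros((16, 16)))
        g.magnitude[:] = 0.0
        g.orientation[:] = 0.0
        g.magnitude[5, 5] = 2.0
        g.orientation[5, 5] = 45.0
        out = cell_histograms(g, HOGConfig(resize_width=16, resize_height=16))
        np.testing.assert_array_equal(out.hist[0, 0], [0, 2.0, 0, 0, 0, 0])

    def test_matches_binning_oracle(self, rng):
        cfg = HOGConfig(resize_width=32, resize_height=32)
        img = rng.uniform(0, 255, size=(32, 32))
        g = compute_gradients(img)
        out = cell_histograms(g, cfg)
        expected = cell_histograms_loops(g.magnitude, g.orientation, 16, 16, 6)
        np.testing.assert_allclose(out.hist, expected, atol=1e-12)

    def test_vote_conservation(self, rng):
        # total votes equal total magnitude over the covered pixels
        cfg = HOGConfig(resize_width=48, resize_height=40, cell_width=16,
                        cell_height=16)
        img = rng.uniform(0, 255, size=(41, 50))  # partial cells get dropped
        g = compute_gradients(img)
        out = cell_histograms(g, cfg)
        covered = g.magnitude[:32, :48]
        assert out.hist.shape == (2, 3, 6)
        np.testing.assert_allclose(out.hist.sum(), covered.sum(), rtol=1e-12)

    def test_cell_larger_than_image_errors(self):
        g = compute_gradients(np.zeros((8, 8)))
        with pytest.raises(HOGConfigError):
            cell_histograms(g, HOGConfig(resize_width=16, resize_height=16))


class TestBlockNormalize:
    def test_default_dimension_504(self, rng):
        img = rng.uniform(0, 255, size=(128, 64))
        g = compute_gradients(img)
        desc = block_normalize(cell_histograms(g, HOGConfig()), HOGConfig())
        assert len(desc) == 504

    def test_zero_cells_give_zero_descriptor(self):
        g = compute_gradients(np.zeros((128, 64)))
        desc = block_normalize(cell_histograms(g, HOGConfig()), HOGConfig())
        assert len(desc) == 504
        assert np.all(desc.vector == 0)
        assert np.all(np.isfinite(desc.vector))

    def test_one_hot_block_normalizes_to_unit(self):
        cfg = HOGConfig(resize_width=32, resize_height=32)
        from hogseg.hog import CellHistogramGrid

        hist = np.zeros((2, 2, 6))
        hist[0, 1, 3] = 5.0
        desc = block_normalize(CellHistogramGrid(hist=hist), cfg)
        v = desc.vector
        assert len(v) == 24
        assert v.max() == pytest.approx(1.0, abs=1e-8)
        assert np.count_nonzero(v) == 1


class TestFullDescriptor:
    @pytest.mark.parametrize("cell,expected", [(16, 504), (12, 864), (8, 2520)])
    def test_printed_dimensions(self, rng, cell, expected):
        cfg = HOGConfig(cell_width=cell, cell_height=cell)
        img = rng.integers(0, 256, size=(50, 70, 3), dtype=np.uint8)
        assert descriptor_length(cfg) == expected
        assert len(hog_descriptor(img, cfg)) == expected

    def test_bin_width_30_degrees(self):
        assert HOGConfig().bin_width == pytest.approx(30.0)

    def test_matches_full_pipeline_oracle(self, rng):
        # random small grayscale grids, no resize involved
        for _ in range(10):
            h = int(rng.integers(24, 64))
            w = int(rng.integers(24, 64))
            cfg = HOGConfig(resize_width=w, resize_height=h, cell_width=8,
                            cell_height=8)
            gray = rng.uniform(0, 255, size=(h, w))
            grad = compute_gradients(gray)
            got = block_normalize(cell_histograms(grad, cfg), cfg).vector
            expected = hog_descriptor_loops(gray, cfg)
            np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_photometric_invariance(self, rng):
        # scaling intensities by c > 0 leaves normalized blocks unchanged
        cfg = HOGConfig(resize_width=32, resize_height=32, cell_width=8,
                        cell_height=8, norm_eps=1e-7)
        gray = rng.uniform(10, 100, size=(32, 32))
        base = block_normalize(cell_histograms(compute_gradients(gray), cfg),
                               cfg).vector
        scaled = block_normalize(
            cell_histograms(compute_gradients(gray * 3.0), cfg), cfg).vector
        np.testing.assert_allclose(scaled, base, atol=1e-5)

    def test_entries_bounded_and_blocks_near_unit(self, rng):
        img = rng.integers(0, 256, size=(90, 90, 3), dtype=np.uint8)
        desc = hog_descriptor(img, HOGConfig())
        assert np.all(desc.vector >= 0)
        assert np.all(desc.vector <= 1.0 + 1e-6)
        segs = desc.vector.reshape(-1, 24)
        norms = np.linalg.norm(segs, axis=1)
        assert np.all(norms <= 1.0 + 1e-6)

    def test_determinism(self):
        img, _ = generate_scene(SceneConfig(seed=1), 0)
        a = hog_descriptor(img).vector
        b = hog_descriptor(img.copy()).vector
        np.testing.assert_array_equal(a, b)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        w=st.integers(16, 96), h=st.integers(16, 96),
        cell=st.integers(4, 16), k=st.integers(2, 9),
        b=st.integers(1, 3), stride=st.integers(1, 2),
    )
    def test_length_law(self, w, h, cell, k, b, stride):
        # closed-form length equals the actual vector length for any config
        if w // cell < b or h // cell < b:
            return
        cfg = HOGConfig(resize_width=w, resize_height=h, cell_width=cell,
                        cell_height=cell, n_bins=k, block_cells=b,
                        block_stride=stride)
        img = np.random.default_rng(0).integers(
            0, 256, size=(h, w, 3), dtype=np.uint8)
        assert len(hog_descriptor(img, cfg)) == descriptor_length(cfg)


class TestGrayscale:
    def test_luminance_weights(self):
        img = np.zeros((2, 2, 3))
        img[..., 1] = 100.0
        np.testing.assert_allclose(to_grayscale(img), 58.7)

    def test_passthrough_2d(self):
        g = np.arange(6.0).reshape(2, 3)
        np.testing.assert_array_equal(to_grayscale(g), g)


class TestBatchExtract:
    def test_store_roundtrip(self, tmp_path, rng):
        from PIL import Image

        paths = []
        for i in range(3):
            img = rng.integers(0, 256, size=(40, 30, 3), dtype=np.uint8)
            p = tmp_path / f"img{i}.png"
            Image.fromarray(img).save(p)
            paths.append(p)
        store = tmp_path / "store.h5"
        status = batch_extract(paths, HOGConfig(), store)
        assert all(status.values()) and len(status) == 3
        vecs = read_store_vectors(store)
        assert set(vecs) == {"img0", "img1", "img2"}
        assert all(v.shape == (504,) for v in vecs.values())
        assert read_store_config(store) == HOGConfig()

    def test_empty_list_gives_valid_empty_store(self, tmp_path):
        store = tmp_path / "empty.h5"
        assert batch_extract([], HOGConfig(), store) == {}
        assert read_store_vectors(store) == {}
        assert read_store_config(store) == HOGConfig()

    def test_rerun_is_bit_identical(self, tmp_path):
        from PIL import Image

        img, _ = generate_scene(SceneConfig(seed=2), 0)
        p = tmp_path / "a.png"
        Image.fromarray(img).save(p)
        s1, s2 = tmp_path / "s1.h5", tmp_path / "s2.h5"
        batch_extract([p], HOGConfig(), s1)
        batch_extract([p], HOGConfig(), s2)
        np.testing.assert_array_equal(read_store_vectors(s1)["a"],
                                      read_store_vectors(s2)["a"])

    def test_unreadable_image_reported_not_fatal(self, tmp_path):
        from PIL import Image

        good = tmp_path / "good.png"
        Image.fromarray(np.zeros((8, 8, 3), dtype=np.uint8)).save(good)
        bad = tmp_path / "bad.png"
        bad.write_bytes(b"not a png")
        store = tmp_path / "s.h5"
        status = batch_extract([good, bad], HOGConfig(), store)
        assert status == {"good": True, "bad": False}
        assert set(read_store_vectors(store)) == {"good"}


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"cell_width": 0}, {"n_bins": -1}, {"cell_width": 80},
        {"norm_eps": 0.0}, {"block_cells": 0},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(HOGConfigError):
            HOGConfig(**kwargs)
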