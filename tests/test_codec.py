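"""Encode/decode target mathematics, checked against brute-force oracles."""

import numpy as np
import pytest

from paddycount.codec import (
    CountMap,
    ClassMap,
    DensityConfig,
    DotAnnotation,
    PatchGrid,
    QuantizerSpec,
    class_count_value,
    class_map_from_count_map,
    count_map_from_density,
    density_from_dots,
    dequantize_class_map,
    deredundancy,
    quantize_count,
    rasterize_dots,
    total_count,
)

SPEC = QuantizerSpec(s=0.1, q=-2.0, c_max=200)


# ---------------------------------------------------------------- oracles

def brute_force_density(dot_grid, sigma, radius):
    """Naive per-dot kernel accumulation, cell by cell."""
    rows, cols = dot_grid.shape
    out = np.zeros((rows, cols))
    for i in range(rows):
        for j in range(cols):
            if dot_grid[i, j] == 0:
                continue
            k = np.zeros((rows, cols))
            for r in range(max(0, i - radius), min(rows, i + radius + 1)):
                for c in range(max(0, j - radius), min(cols, j + radius + 1)):
                    k[r, c] = np.exp(-((r - i) ** 2 + (c - j) ** 2) / (2 * sigma**2))
            out += dot_grid[i, j] * k / k.sum()
    return out


def brute_force_count_map(density, block, stride):
    """Double-loop window sums over fully contained patches."""
    rows, cols = density.shape
    nr = (rows - block) // stride + 1
    nc = (cols - block) // stride + 1
    out = np.zeros((nr, nc))
    for i in range(nr):
        for j in range(nc):
            out[i, j] = density[i * stride : i * stride + block, j * stride : j * stride + block].sum()
    return out


def brute_force_deredundancy(values, block, stride, shape):
    """Accumulate per-pixel spread then divide by coverage, pixel by pixel."""
    acc = np.zeros(shape)
    cov = np.zeros(shape)
    nr, nc = values.shape
    for i in range(nr):
        for j in range(nc):
            for r in range(i * stride, i * stride + block):
                for c in range(j * stride, j * stride + block):
                    acc[r, c] += values[i, j] / (block * block)
                    cov[r, c] += 1
    return np.divide(acc, cov, out=np.zeros(shape), where=cov > 0)


# ---------------------------------------------------------------- rasterize

class TestRasterizeDots:
    def test_empty_annotation_gives_zero_grid(self):
        grid = rasterize_dots(DotAnnotation("a"), (8, 8))
        assert grid.shape == (8, 8) and grid.sum() == 0

    def test_rounding_places_dot_at_nearest_pixel(self):
        grid = rasterize_dots(DotAnnotation("a", [(3.2, 5.7)]), (8, 8))
        assert grid[6, 3] == 1 and grid.sum() == 1

    def test_coincident_points_keep_multiplicity(self):
        grid = rasterize_dots(DotAnnotation("a", [(2.0, 2.0), (2.0, 2.0)]), (4, 4))
        assert grid[2, 2] == 2 and grid.sum() == 2

    def test_scale_rescales_coordinates(self):
        grid = rasterize_dots(DotAnnotation("a", [(8.0, 12.0)]), (4, 4), scale=0.25)
        assert grid[3, 2] == 1

    def test_out_of_bounds_clamped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            grid = rasterize_dots(DotAnnotation("a", [(7.9, 3.0)]), (8, 8))
        assert grid[3, 7] == 1 and "clamped" in caplog.text

    @pytest.mark.parametrize(
        "shape,points,err",
        [((0, 8), [], "positive"), ((8, 8), [(-1.0, 2.0)], "negative")],
    )
    def test_invalid_inputs_raise(self, shape, points, err):
        with pytest.raises(ValueError, match=err):
            rasterize_dots(DotAnnotation("a", points), shape)


# ---------------------------------------------------------------- density

class TestDensityFromDots:
    def test_center_dot_mass_one_and_peak_at_dot(self):
        grid = np.zeros((33, 33))
        grid[16, 16] = 1
        d = density_from_dots(grid, DensityConfig(sigma=4))
        assert d.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.unravel_index(d.argmax(), d.shape) == (16, 16)

    def test_corner_dot_renormalized_to_unit_mass(self):
        grid = np.zeros((16, 16))
        grid[0, 0] = 1
        d = density_from_dots(grid, DensityConfig(sigma=4))
        assert d.sum() == pytest.approx(1.0, abs=1e-6)

    def test_matches_brute_force_oracle(self, rng):
        grid = np.zeros((64, 64))
        idx = rng.choice(64 * 64, size=7, replace=False)
        grid[np.unravel_index(idx, grid.shape)] = 1
        cfg = DensityConfig(sigma=4)
        d = density_from_dots(grid, cfg)
        assert d.sum() == pytest.approx(7.0, abs=1e-6)
        expected = brute_force_density(grid, 4.0, cfg.radius)
        np.testing.assert_allclose(d, expected, atol=1e-12)

    def test_bad_sigma_rejected(self):
        with pytest.raises(ValueError, match="sigma"):
            DensityConfig(sigma=0)


# ---------------------------------------------------------------- count map

class TestCountMap:
    def test_uniform_field_non_overlapping(self):
        cm = count_map_from_density(np.full((16, 16), 0.5), block=8, stride=8)
        assert cm.values.shape == (2, 2)
        np.testing.assert_allclose(cm.values, 32.0)

    def test_uniform_field_overlapping(self):
        cm = count_map_from_density(np.full((16, 16), 0.5), block=8, stride=4)
        assert cm.values.shape == (3, 3)
        np.testing.assert_allclose(cm.values, 32.0)

    def test_matches_brute_force_window_sums(self, rng):
        density = rng.random((40, 40))
        cm = count_map_from_density(density, block=32, stride=8)
        assert cm.values.shape == (2, 2)
        np.testing.assert_allclose(cm.values, brute_force_count_map(density, 32, 8), atol=1e-6)

    def test_image_smaller_than_block_raises_with_minimum(self):
        with pytest.raises(ValueError, match=r"\(32, 32\)"):
            count_map_from_density(np.zeros((20, 40)), block=32, stride=8)

    def test_partition_identity_when_aligned(self, rng):
        grid = np.zeros((64, 64))
        grid[rng.integers(8, 56, 10), rng.integers(8, 56, 10)] = 1
        density = density_from_dots(grid)
        cm = count_map_from_density(density, block=16, stride=16)
        assert cm.values.sum() == pytest.approx(density.sum(), abs=1e-6)


# ---------------------------------------------------------------- quantizer

class TestQuantizer:
    def test_zero_count_is_class_zero(self):
        assert quantize_count(0.0, SPEC) == 0

    def test_log_space_boundaries(self):
        assert quantize_count(np.exp(-2.0), SPEC) == 2
        assert quantize_count(0.05, SPEC) == 1

    def test_monotone_over_log_grid(self):
        ns = np.logspace(-3, 3, 500)
        cls = quantize_count(ns, SPEC)
        assert np.all(np.diff(cls) >= 0)

    def test_cap_at_c_max(self):
        spec = QuantizerSpec(s=0.1, q=-2.0, c_max=5)
        assert quantize_count(1e6, spec) == 5

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            quantize_count(-1.0, SPEC)

    def test_boundaries_strictly_increasing(self):
        cs = np.arange(2, 50)
        nt = SPEC.boundary(cs)
        assert np.all(np.diff(nt) > 0)

    def test_for_max_count_leaves_headroom(self):
        spec = QuantizerSpec.for_max_count(50.0)
        assert quantize_count(50.0, spec) < spec.c_max


class TestClassMap:
    def test_all_zero_counts_give_all_zero_classes(self):
        cm = count_map_from_density(np.zeros((16, 16)), 8, 8)
        assert not class_map_from_count_map(cm, SPEC).values.any()

    def test_elementwise_matches_scalar_quantizer(self):
        grid = PatchGrid(block=8, stride=8, image_shape=(16, 16))
        counts = CountMap(np.array([[0.0, 0.05], [0.5, 3.0]]), grid)
        cm = class_map_from_count_map(counts, SPEC)
        expected = [[0, 1], [quantize_count(0.5, SPEC), quantize_count(3.0, SPEC)]]
        np.testing.assert_array_equal(cm.values, expected)

    def test_values_always_within_range(self, rng):
        grid = PatchGrid(block=8, stride=8, image_shape=(32, 32))
        counts = CountMap(rng.random((4, 4)) * 1e4, grid)
        spec = QuantizerSpec(s=0.1, q=-2.0, c_max=10)
        cm = class_map_from_count_map(counts, spec)
        assert cm.values.min() >= 0 and cm.values.max() <= 10


class TestInverseQuantization:
    def test_class_zero_decodes_to_zero(self):
        assert class_count_value(0, SPEC) == 0.0

    def test_class_one_is_half_of_exp_q(self):
        assert class_count_value(1, SPEC) == pytest.approx(np.exp(-2.0) / 2, rel=1e-12)

    def test_decoded_value_lies_in_its_interval(self):
        for n in np.logspace(-1.9, 2, 50):
            c = quantize_count(n, SPEC)
            v = class_count_value(c, SPEC)
            assert SPEC.boundary(c) <= v < SPEC.boundary(c + 1)

    def test_out_of_range_class_rejected(self):
        with pytest.raises(ValueError, match="class index"):
            class_count_value(SPEC.c_max + 1, SPEC)

    def test_roundtrip_relative_error_bound(self):
        bound = (np.exp(SPEC.s) - 1) / 2 + 1e-9
        ns = np.logspace(np.log10(np.exp(SPEC.q)) + 1e-9, np.log10(50), 400)
        grid = PatchGrid(block=8, stride=8, image_shape=(8, 8 * len(ns)))
        counts = CountMap(ns[None, :], grid)
        decoded = dequantize_class_map(class_map_from_count_map(counts, SPEC))
        rel = np.abs(decoded.values - ns) / ns
        assert rel.max() <= bound

    def test_single_cell_class_one(self):
        grid = PatchGrid(block=8, stride=8, image_shape=(8, 8))
        cm = ClassMap(np.array([[1]]), grid, SPEC)
        assert dequantize_class_map(cm).values[0, 0] == pytest.approx(np.exp(-2.0) / 2)


# ---------------------------------------------------------------- decode

class TestDeredundancy:
    def test_single_patch_spreads_evenly(self):
        grid = PatchGrid(block=4, stride=4, image_shape=(4, 4))
        px = deredundancy(CountMap(np.array([[4.0]]), grid))
        np.testing.assert_allclose(px.values, 0.25)
        assert px.total() == pytest.approx(4.0)

    def test_uniform_overlapping_field_interior(self):
        grid = PatchGrid(block=32, stride=8, image_shape=(64, 64))
        counts = CountMap(np.full(grid.n_patches, 5.0), grid)
        px = deredundancy(counts)
        interior = px.values[31:33, 31:33]
        np.testing.assert_allclose(interior, 5.0 / 1024)

    def test_matches_brute_force_accumulate_then_divide(self, rng):
        grid = PatchGrid(block=8, stride=4, image_shape=(12, 12))
        counts = CountMap(rng.random((2, 2)) * 10, grid)
        px = deredundancy(counts)
        expected = brute_force_deredundancy(counts.values, 8, 4, (12, 12))
        np.testing.assert_allclose(px.values, expected, atol=1e-9)

    def test_empty_count_map_raises(self):
        grid = PatchGrid(block=8, stride=8, image_shape=(8, 8))
        cm = CountMap(np.zeros((1, 1)), grid)
        cm.values = np.zeros((0, 0))
        with pytest.raises(ValueError, match="empty"):
            deredundancy(cm)

    def test_unaligned_margin_is_zero(self):
        grid = PatchGrid(block=8, stride=8, image_shape=(12, 12))
        px = deredundancy(CountMap(np.array([[8.0]]), grid))
        assert px.values[8:, :].sum() == 0 and px.values[:, 8:].sum() == 0


class TestTotalCount:
    def test_zero_map(self):
        grid = PatchGrid(block=8, stride=8, image_shape=(16, 16))
        assert total_count(CountMap(np.zeros((2, 2)), grid)) == 0.0

    def test_overlapping_count_map_rejected(self):
        grid = PatchGrid(block=8, stride=4, image_shape=(16, 16))
        with pytest.raises(ValueError, match="deredundancy"):
            total_count(CountMap(np.zeros((3, 3)), grid))

    def test_conservation_chain_from_dots(self, rng):
        grid = np.zeros((64, 64))
        pos = rng.integers(16, 48, size=(7, 2))
        for r, c in pos:
            grid[r, c] += 1
        density = density_from_dots(grid)
        cm = count_map_from_density(density, block=32, stride=32)
        assert total_count(cm) == pytest.approx(7.0, abs=1e-6)

    def test_exact_decode_conservation_interior_dots(self, rng):
        # ground-truth patch counts through the overlapping decode
        grid = np.zeros((128, 128))
        pos = rng.integers(48, 80, size=(12, 2))
        for r, c in pos:
            grid[r, c] += 1
        density = density_from_dots(grid)
        cm = count_map_from_density(density, block=32, stride=8)
        assert deredundancy(cm).total() == pytest.approx(12.0, abs=0.5)
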