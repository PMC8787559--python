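"""Count/size distribution fitting and ellipse mask simulation."""

import math

import numpy as np
import pytest

from nucleifuse import (
    CountModel,
    EllipseSpec,
    SizeModel,
    fit_count_model,
    fit_size_model,
    generate_dataset,
    instance_areas,
    normalize_ids,
    rasterize_ellipse,
    sample_mask_image,
)

EULER_GAMMA = float(np.euler_gamma)


def constant_count_maps(counts, shape=(40, 40)):
    """One map per requested count, nuclei as separated 2x3 blocks."""
    maps = []
    for n in counts:
        m = np.zeros(shape, dtype=np.int64)
        for i in range(n):
            r, c = divmod(i, 10)
            m[4 * r : 4 * r + 2, 4 * c : 4 * c + 3] = i + 1
        maps.append(m)
    return maps


class TestFitCountModel:
    def test_constant_counts(self):
        cm = fit_count_model(constant_count_maps([10, 10, 10]))
        assert cm.mean == 10 and cm.sd == 0

    def test_sample_standard_deviation(self):
        cm = fit_count_model(constant_count_maps([8, 12]))
        assert cm.mean == pytest.approx(10)
        assert cm.sd == pytest.approx(2 * math.sqrt(2))

    def test_single_map_is_an_error(self):
        with pytest.raises(ValueError):
            fit_count_model(constant_count_maps([5]))


class TestFitSizeModel:
    def test_method_of_moments_inversion(self):
        # a sample with mean 111.544 and sd 25.650 inverts to (mu, beta)
        # ~ (100, 20): beta = sd*sqrt(6)/pi, mu = mean - gamma*beta
        beta = 20.0
        mu = 100.0
        sd = beta * math.pi / math.sqrt(6)
        mean = mu + EULER_GAMMA * beta
        # two-level 10-point sample with that mean and (ddof=1) sd:
        # points mean +- d with d = sd * sqrt((n-1)/n)
        d = sd * math.sqrt(9 / 10)
        lo, hi = mean - d, mean + d
        m = np.zeros((60, 4000), dtype=np.int64)
        col = 0
        for i, a in enumerate([round(lo)] * 5 + [round(hi)] * 5):
            m[2 * (i % 20), col : col + int(a)] = i + 1
            col += int(a) + 2
        model = fit_size_model([m])
        arr = np.array([round(lo)] * 5 + [round(hi)] * 5, dtype=float)
        expected_beta = arr.std(ddof=1) * math.sqrt(6) / math.pi
        expected_mu = arr.mean() - EULER_GAMMA * expected_beta
        assert model.scale == pytest.approx(expected_beta)
        assert model.location == pytest.approx(expected_mu)
        assert model.scale == pytest.approx(20.0, abs=0.5)
        assert model.location == pytest.approx(100.0, abs=1.0)

    def test_monte_carlo_recovery_from_gumbel_draws(self):
        # n = 1e4 integer areas drawn from Gumbel(100, 20), packed into
        # instance maps as one-row runs: the method-of-moments fit
        # recovers mu within +-2 and beta within +-1 (3 standard errors)
        rng = np.random.default_rng(77)
        areas = np.round(rng.gumbel(100, 20, size=10_000)).astype(int)
        areas = areas[areas >= 1]
        maps = []
        for chunk in np.array_split(areas, 10):
            m = np.zeros((2 * len(chunk), int(chunk.max()) + 1), dtype=np.int64)
            for i, a in enumerate(chunk):
                m[2 * i, :a] = i + 1
            maps.append(m)
        model = fit_size_model(maps, min_area=1)
        assert model.location == pytest.approx(100, abs=2)
        assert model.scale == pytest.approx(20, abs=1)

    def test_degenerate_constant_areas(self):
        maps = constant_count_maps([12, 12])  # all nuclei 6 px
        with pytest.raises(ValueError, match="sd = 0"):
            fit_size_model(maps, min_area=1)

    def test_too_few_nuclei_is_an_error(self):
        with pytest.raises(ValueError):
            fit_size_model(constant_count_maps([2, 2]))


class TestEllipseGeometry:
    def test_semi_axes_preserve_area(self):
        spec = EllipseSpec(center=(10, 10), area=80.0, orientation=0.7, axis_ratio=1.8)
        a, b = spec.semi_axes
        assert math.pi * a * b == pytest.approx(80.0)
        assert a / b == pytest.approx(1.8)

    def test_rasterized_area_tracks_requested_area(self, rng):
        # statistical rasterization fidelity: pixel count within 15% of the
        # requested area for areas >= 35
        errors = []
        for _ in range(1000):
            s = float(rng.uniform(35, 400))
            spec = EllipseSpec(
                center=(32 + rng.uniform(-2, 2), 32 + rng.uniform(-2, 2)),
                area=s,
                orientation=float(rng.uniform(0, math.pi)),
                axis_ratio=float(rng.uniform(1.0, 2.5)),
            )
            n_px = int(rasterize_ellipse(spec, (64, 64)).sum())
            errors.append(abs(n_px - s) / s)
        assert max(errors) < 0.15

    def test_rasterization_clips_to_image(self):
        spec = EllipseSpec(center=(0, 0), area=100.0, orientation=0.0, axis_ratio=1.0)
        mask = rasterize_ellipse(spec, (20, 20))
        assert 0 < mask.sum() < 100  # roughly a quarter survives


class TestSampleMaskImage:
    def test_zero_count_model_gives_empty_map(self):
        m = sample_mask_image(CountModel(0, 0), SizeModel(100, 20), (64, 64), rng_seed=1)
        assert m.max() == 0

    def test_determinism_under_fixed_seed(self):
        count, size = CountModel(20, 4), SizeModel(100, 20)
        a = sample_mask_image(count, size, (128, 128), rng_seed=9)
        b = sample_mask_image(count, size, (128, 128), rng_seed=9)
        assert np.array_equal(a, b)

    def test_count_statistics_over_many_images(self):
        # per-image nucleus count tracks the Gaussian mean within 1.0
        # over 200 images (rejection losses under 5% at zero overlap)
        count, size = CountModel(30, 5), SizeModel(100, 20)
        maps = generate_dataset(200, count, size, shape=(256, 256), rng_seed=100)
        counts = [len(instance_areas(m)) for m in maps]
        assert np.mean(counts) == pytest.approx(30, abs=1.0)

    def test_outputs_are_valid_instance_maps(self):
        m = sample_mask_image(CountModel(25, 5), SizeModel(100, 20), (128, 128), rng_seed=4)
        assert np.array_equal(m, normalize_ids(m))

    def test_min_gap_enforces_separation(self):
        from scipy import ndimage as ndi

        m = sample_mask_image(
            CountModel(30, 0), SizeModel(100, 20), (160, 160), min_gap=2, rng_seed=6
        )
        for i in instance_areas(m):
            grown = ndi.binary_dilation(m == i, np.ones((3, 3), bool), iterations=2)
            assert not (m[grown] * (m[grown] != i)).any()

    def test_fit_sample_loop_recovers_generating_distribution(self):
        # generate ~3e3 areas, refit, land within 3 standard errors
        count, size = CountModel(30, 5), SizeModel(100, 20)
        maps = generate_dataset(100, count, size, keep_inside=True, rng_seed=55)
        model = fit_size_model(maps)
        n = sum(len(instance_areas(m)) for m in maps)
        sigma = 20 * math.pi / math.sqrt(6)
        se_beta = 20 * 1.05 / math.sqrt(n)
        se_mu = sigma / math.sqrt(n) + EULER_GAMMA * se_beta
        assert abs(model.location - 100) < 3 * se_mu + 0.5  # + rasterization slack
        assert abs(model.scale - 20) < 3 * se_beta + 0.5

    def test_dataset_determinism_and_independence(self):
        count, size = CountModel(10, 2), SizeModel(100, 20)
        d1 = generate_dataset(3, count, size, shape=(96, 96), rng_seed=21)
        d2 = generate_dataset(3, count, size, shape=(96, 96), rng_seed=21)
        assert all(np.array_equal(a, b) for a, b in zip(d1, d2))
        assert not np.array_equal(d1[0], d1[1])

    def test_tiny_shape_is_an_error(self):
        with pytest.raises(ValueError):
            sample_mask_image(CountModel(1, 0), SizeModel(100, 20), (8, 8))
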