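"""Calibrated generator: moment matching, determinism, rendering geometry."""

import math

import numpy as np
import pytest

from nucdhl.calibration import get_stats, inferred_population_size, percent_shift
from nucdhl.exceptions import ArgumentError, ConfigurationError
from nucdhl.morphometry import compute_morphometrics, fit_ellipse
from nucdhl.synthetic import (
    generate_dataset,
    generate_population,
    render_nucleus,
    write_dataset,
)
from nucdhl.types import GroupStats, RenderStyle


class TestCalibrationTable:
    def test_inferred_sample_sizes(self):
        # n = round((sd/sem)^2); the lamin-A area rows give the study sizes
        assert inferred_population_size("normal", "laminA") == 338
        assert inferred_population_size("cancer", "laminA") == 393

    def test_groupstats_infers_n(self):
        gs = GroupStats(parameter="area", group="normal", stain="laminA",
                        mean=10.0, sem=0.5, sd=5.0)
        assert gs.n == 100

    def test_unknown_cell_raises(self):
        with pytest.raises(ConfigurationError):
            get_stats("area", "normal", "laminC")

    def test_eccentricity_shift_matches_reported_magnitude(self):
        # the normal->cancer eccentricity mean shift is ~12% for lamin A
        assert percent_shift("eccentricity", "laminA") == pytest.approx(11.57, abs=0.05)


class TestGeneratePopulation:
    def test_empty(self):
        assert generate_population("normal", "laminA", 0, seed=1) == []

    def test_negative_n(self):
        with pytest.raises(ArgumentError):
            generate_population("normal", "laminA", -1, seed=1)

    def test_unknown_group(self):
        with pytest.raises(ConfigurationError):
            generate_population("benign", "laminA", 3, seed=1)

    def test_determinism(self):
        one = generate_population("cancer", "laminB", 50, seed=9)
        two = generate_population("cancer", "laminB", 50, seed=9)
        assert one == two

    def test_geometry_invariants(self):
        for geom in generate_population("cancer", "laminA", 500, seed=5):
            assert geom.a >= geom.b > 0
            assert 0.0 <= geom.theta < math.pi
            assert geom.label == "cancer" and geom.stain == "laminA"

    def test_sample_mean_area_at_study_size(self):
        # n=338 normal lamin-A nuclei: sample mean area within 2 SEM of 23.47
        pop = generate_population("normal", "laminA", 338, seed=0)
        mean_area = np.mean([math.pi * g.a * g.b for g in pop])
        stats = get_stats("area", "normal", "laminA")
        assert abs(mean_area - stats.mean) <= 2.0 * stats.sem

    def test_law_of_large_numbers_perimeter(self):
        # moment-matched sampler: mean perimeter converges to the printed mean
        pop = generate_population("cancer", "laminA", 50_000, seed=123)
        per = np.mean([compute_morphometrics(g).perimeter for g in pop])
        assert abs(per / get_stats("perimeter", "cancer", "laminA").mean - 1.0) < 0.02


class TestRenderNucleus:
    def test_refit_recovers_axes_on_noiseless_raster(self, example_nucleus, clean_style):
        img = render_nucleus(example_nucleus, clean_style, seed=1)
        mask = img.pixels[:, :, 0] > clean_style.fill_intensity / 2.0
        fit = fit_ellipse(mask, img.pixel_size)
        assert fit.a == pytest.approx(example_nucleus.a, rel=0.02)
        assert fit.b == pytest.approx(example_nucleus.b, rel=0.02)

    def test_determinism_and_shape(self, example_nucleus, noisy_style):
        one = render_nucleus(example_nucleus, noisy_style, seed=7)
        two = render_nucleus(example_nucleus, noisy_style, seed=7)
        assert np.array_equal(one.pixels, two.pixels)
        assert one.pixels.shape == (noisy_style.image_size, noisy_style.image_size, 2)
        assert one.pixels.min() >= 0.0 and one.pixels.max() <= 1.0

    def test_large_nucleus_rescaled_to_fit(self, clean_style):
        big = generate_population("cancer", "laminA", 1, seed=3)[0]
        huge = type(big)(a=30.0, b=20.0, label="cancer", stain="laminA")
        img = render_nucleus(huge, clean_style, seed=0)
        # effective pixel size grew so the ellipse still fits
        assert img.pixel_size > clean_style.pixel_size
        border = np.concatenate([img.pixels[0, :, 0], img.pixels[-1, :, 0],
                                 img.pixels[:, 0, 0], img.pixels[:, -1, 0]])
        assert border.max() < clean_style.fill_intensity / 2.0


class TestGenerateDataset:
    def test_bookkeeping(self, clean_style):
        images, table, truths = generate_dataset(10, "laminA", clean_style, seed=2)
        assert len(images) == len(table) == len(truths) == 20
        labels = [img.label for img in images]
        assert labels.count("normal") == labels.count("cancer") == 10
        for img, rec, geom in zip(images, table, truths):
            assert img.label == rec.label == geom.label

    def test_index_alignment_of_morphometrics(self, clean_style):
        _, table, truths = generate_dataset(5, "laminB", clean_style, seed=4)
        for rec, geom in zip(table, truths):
            assert rec.area == pytest.approx(math.pi * geom.a * geom.b, rel=1e-12)

    def test_cancer_area_mean_at_scale(self, clean_style):
        small = RenderStyle(image_size=32, psf_sigma=0.0, noise_sd=0.0,
                            background_gradient_amplitude=0.0)
        _, table, _ = generate_dataset(5000, "laminA", small, seed=6)
        cancer_area = np.mean([r.area for r in table if r.label == "cancer"])
        assert cancer_area == pytest.approx(51.62, rel=0.03)

    def test_csv_determinism(self, tmp_path, clean_style):
        payloads = []
        for rerun in ("one", "two"):
            out = tmp_path / rerun
            images, table, truths = generate_dataset(4, "laminA", clean_style, seed=8)
            write_dataset(out, images, table, truths)
            payloads.append((out / "morphometrics.csv").read_bytes())
            assert (out / "laminA_normal_0.tif").exists()
            assert (out / "laminA_cancer_7.png").exists()
        assert payloads[0] == payloads[1]
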