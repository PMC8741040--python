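"""Conditioning-chain contracts: masking, sharpening, background removal,
normalisation, and tabular standardisation."""

import numpy as np
import pandas as pd
import pytest

from nucdhl.exceptions import ArgumentError, ScalingError, SegmentationError
from nucdhl.preprocessing import (
    PreprocessParams,
    build_segmentation_mask,
    preprocess,
    sharpen,
    standard_scale,
)
from nucdhl.synthetic import render_nucleus
from nucdhl.types import EllipseNucleus, NucleusImage

from conftest import make_image


class TestSegmentationMask:
    def test_all_zero_image_gives_empty_mask(self):
        img = make_image(np.zeros((64, 64)))
        assert build_segmentation_mask(img).sum() == 0

    def test_iou_against_ground_truth_raster(self, clean_style):
        geom = EllipseNucleus(a=6.0, b=4.0, theta=1.0)
        img = render_nucleus(geom, clean_style, seed=0)
        mask = build_segmentation_mask(img, PreprocessParams(sensitivity=0.5))
        size = clean_style.image_size
        half = size * img.pixel_size / 2.0
        coords = (np.arange(size) + 0.5) * img.pixel_size - half
        x, y = np.meshgrid(coords, coords)
        xr = np.cos(geom.theta) * x + np.sin(geom.theta) * y
        yr = -np.sin(geom.theta) * x + np.cos(geom.theta) * y
        truth = (xr / geom.a) ** 2 + (yr / geom.b) ** 2 <= 1.0
        inter = np.logical_and(mask, truth).sum()
        union = np.logical_or(mask, truth).sum()
        assert inter / union >= 0.90

    def test_closing_fills_interior_hole(self):
        plane = np.zeros((64, 64))
        plane[20:40, 20:40] = 1.0
        plane[30, 30] = 0.0  # 1-pixel hole
        img = make_image(plane)
        params = PreprocessParams(closing_kernel_radius=2)
        mask = build_segmentation_mask(img, params)
        assert mask[30, 30] == 1
        # closing is extensive here: it never removes thresholded pixels
        assert np.all(mask[plane >= 0.5] == 1)


class TestSharpen:
    def test_constant_image_unchanged(self):
        img = make_image(np.full((48, 48), 0.4))
        out = sharpen(img)
        assert np.allclose(out.pixels, 0.4, atol=1e-9)

    def test_step_edge_contrast_increases(self):
        plane = np.zeros((48, 48))
        plane[:, 24:] = 0.6
        img = make_image(plane)
        out = sharpen(img, PreprocessParams(blur_sigma=1.5))
        row_in, row_out = plane[24], out.pixels[24]
        assert (row_out.max() - row_out.min()) >= (row_in.max() - row_in.min())

    def test_output_clipped(self):
        rng = np.random.default_rng(0)
        img = make_image(rng.random((40, 40)))
        out = sharpen(img)
        assert out.pixels.min() >= 0.0 and out.pixels.max() <= 1.0

    def test_weights_must_preserve_brightness(self):
        with pytest.raises(ArgumentError):
            PreprocessParams(sharpen_weight_original=1.5, sharpen_weight_blurred=-0.4)


class TestPreprocess:
    def test_background_exactly_zero(self, noisy_style, example_nucleus):
        img = render_nucleus(example_nucleus, noisy_style, seed=3)
        params = PreprocessParams()
        out = preprocess(img, params)
        mask = build_segmentation_mask(img, params).astype(bool)
        assert out.provenance == "preprocessed"
        assert np.all(out.pixels[~mask] == 0.0)

    def test_foreground_normalised(self, noisy_style, example_nucleus):
        img = render_nucleus(example_nucleus, noisy_style, seed=4)
        out = preprocess(img)
        fg = out.pixels[out.pixels > 0]
        assert out.pixels.min() == 0.0
        assert fg.max() == pytest.approx(1.0)

    def test_deterministic(self, noisy_style, example_nucleus):
        img = render_nucleus(example_nucleus, noisy_style, seed=5)
        assert np.array_equal(preprocess(img).pixels, preprocess(img).pixels)

    def test_empty_segmentation_rejected(self):
        img = make_image(np.zeros((64, 64)))
        with pytest.raises(SegmentationError):
            preprocess(img)

    def test_near_idempotent_when_mask_stable(self):
        # a binary single-nucleus image keeps its mask stable across passes
        yy, xx = np.mgrid[:64, :64]
        plane = (((xx - 32) ** 2 + (yy - 32) ** 2) <= 15**2).astype(np.float64)
        once = preprocess(make_image(plane))
        twice = preprocess(once)
        changed = np.abs(twice.pixels.astype(np.float64)
                         - once.pixels.astype(np.float64))
        assert changed.max() <= 1e-6


class TestStandardScale:
    def test_hand_arithmetic(self):
        table = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        scaled, _ = standard_scale(table)
        assert np.allclose(scaled["x"], [-1.2247, 0.0, 1.2247], atol=1e-4)

    def test_round_trip(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame(rng.normal(5.0, 2.0, size=(30, 4)),
                             columns=list("abcd"))
        scaled, scaler = standard_scale(table)
        back = scaler.inverse_transform(scaled)
        assert np.allclose(back.to_numpy(), table.to_numpy(), atol=1e-9)
        held_out = pd.DataFrame(rng.normal(5.0, 2.0, size=(5, 4)),
                                columns=list("abcd"))
        assert np.allclose(scaler.inverse_transform(scaler.transform(held_out)),
                           held_out.to_numpy(), atol=1e-9)

    def test_columns_standardised(self):
        rng = np.random.default_rng(2)
        table = pd.DataFrame(rng.lognormal(1.0, 0.4, size=(200, 3)),
                             columns=["area", "perimeter", "eccentricity"])
        scaled, _ = standard_scale(table)
        assert np.allclose(scaled.mean(), 0.0, atol=1e-9)
        assert np.allclose(scaled.to_numpy().std(axis=0), 1.0, atol=1e-9)

    def test_zero_variance_column_named(self):
        table = pd.DataFrame({"good": [1.0, 2.0, 3.0], "flat": [7.0, 7.0, 7.0]})
        with pytest.raises(ScalingError, match="flat"):
            standard_scale(table)
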