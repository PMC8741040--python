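"""Ellipse descriptor formulas against independent closed-form and
quadrature oracles, plus the moment-based ellipse refit."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from nucdhl.exceptions import ArgumentError, EmptyInputError
from nucdhl.morphometry import (
    compute_morphometrics,
    fit_ellipse,
    population_stats,
    ramanujan_perimeter,
    records_to_frame,
)
from nucdhl.synthetic import render_nucleus
from nucdhl.types import EllipseNucleus, MorphometricRecord, RenderStyle


def arc_length_perimeter(a: float, b: float) -> float:
    """Exact ellipse perimeter by numerical quadrature of the arc-length
    integral (independent of the Ramanujan approximation under test)."""
    integrand = lambda t: math.hypot(a * math.sin(t), b * math.cos(t))
    value, _ = quad(integrand, 0.0, math.pi / 2.0, limit=200)
    return 4.0 * value


class TestDescriptors:
    def test_circle_limit(self):
        rec = compute_morphometrics(EllipseNucleus(a=3.0, b=3.0))
        assert rec.area == pytest.approx(28.2743, abs=1e-4)
        assert rec.perimeter == pytest.approx(18.8496, abs=1e-4)
        assert rec.circularity == pytest.approx(1.0, abs=1e-12)
        assert rec.eccentricity == 0.0
        assert rec.foci_distance == 0.0
        assert rec.loop_length == pytest.approx(6.0)
        assert rec.max_curvature == pytest.approx(1.0 / 3.0)

    def test_two_one_ellipse_closed_form(self):
        # a=2, b=1: c=sqrt(3); every descriptor has a hand-derivable value
        rec = compute_morphometrics(EllipseNucleus(a=2.0, b=1.0))
        c = math.sqrt(3.0)
        assert rec.eccentricity == pytest.approx(c / 2.0, abs=1e-12)
        assert rec.foci_distance == pytest.approx(2.0 * c, abs=1e-12)
        assert rec.max_curvature == pytest.approx(2.0, abs=1e-12)
        assert rec.loop_length == pytest.approx(2.0 * (2.0 + c), abs=1e-12)
        assert rec.area == pytest.approx(2.0 * math.pi, abs=1e-12)
        assert rec.normalized_curvature == pytest.approx(2.0 * math.sqrt(2.0), abs=1e-12)
        assert rec.perimeter == pytest.approx(9.6884, abs=1e-3)
        assert rec.perimeter == pytest.approx(arc_length_perimeter(2.0, 1.0), rel=1e-4)

    def test_ramanujan_matches_arc_length_quadrature(self, random_ellipses):
        for geom in random_ellipses:
            exact = arc_length_perimeter(geom.a, geom.b)
            assert float(ramanujan_perimeter(geom.a, geom.b)) == pytest.approx(
                exact, rel=1e-4)

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(ArgumentError):
            EllipseNucleus(a=1.0, b=-1.0)
        with pytest.raises(ArgumentError):
            EllipseNucleus(a=1.0, b=2.0)

    @settings(derandomize=True, max_examples=60)
    @given(b=st.floats(0.5, 5.0), aspect=st.floats(1.0, 10.0),
           scale=st.floats(0.2, 5.0))
    def test_scale_covariance_and_isoperimetric_bound(self, b, aspect, scale):
        base = compute_morphometrics(EllipseNucleus(a=b * aspect, b=b))
        scaled = compute_morphometrics(
            EllipseNucleus(a=b * aspect * scale, b=b * scale))
        assert scaled.area == pytest.approx(base.area * scale**2, rel=1e-9)
        assert scaled.perimeter == pytest.approx(base.perimeter * scale, rel=1e-9)
        assert scaled.foci_distance == pytest.approx(base.foci_distance * scale, rel=1e-9)
        assert scaled.max_curvature == pytest.approx(base.max_curvature / scale, rel=1e-9)
        for invariant in ("circularity", "eccentricity", "normalized_curvature"):
            assert getattr(scaled, invariant) == pytest.approx(
                getattr(base, invariant), rel=1e-9)
        assert base.circularity <= 1.0
        if aspect > 1.0 + 1e-6:
            assert base.circularity < 1.0

    def test_eccentricity_and_foci_distance_monotone_in_a(self):
        b = 2.0
        values = [compute_morphometrics(EllipseNucleus(a=a, b=b))
                  for a in np.linspace(2.0, 10.0, 9)]
        ecc = [v.eccentricity for v in values]
        foci = [v.foci_distance for v in values]
        assert all(x < y for x, y in zip(ecc, ecc[1:]))
        assert all(x < y for x, y in zip(foci, foci[1:]))


class TestFitEllipse:
    def test_round_trip_against_rasterizer(self, clean_style):
        geom = EllipseNucleus(a=10.0, b=5.0, theta=0.6)
        style = RenderStyle(image_size=128, pixel_size=0.2, psf_sigma=0.0,
                            noise_sd=0.0, background_gradient_amplitude=0.0)
        img = render_nucleus(geom, style, seed=0)
        mask = img.pixels[:, :, 0] > style.fill_intensity / 2.0
        fit = fit_ellipse(mask, img.pixel_size)
        assert fit.a == pytest.approx(geom.a, rel=0.02)
        assert fit.b == pytest.approx(geom.b, rel=0.02)

    def test_disk_is_round(self):
        yy, xx = np.mgrid[:96, :96]
        mask = (xx - 48) ** 2 + (yy - 48) ** 2 <= 30**2
        fit = fit_ellipse(mask, pixel_size=1.0)
        assert fit.a == pytest.approx(30.0, rel=0.05)
        assert fit.b == pytest.approx(30.0, rel=0.05)
        assert compute_morphometrics(fit).eccentricity < 0.1

    def test_empty_mask(self):
        with pytest.raises(EmptyInputError):
            fit_ellipse(np.zeros((64, 64), dtype=bool), 1.0)

    def test_too_small_region(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[10:12, 10:12] = True
        with pytest.raises(ArgumentError, match="minimum"):
            fit_ellipse(mask, 1.0)


class TestPopulationStats:
    @staticmethod
    def _records(perimeters):
        return [
            MorphometricRecord(area=10.0, perimeter=p, circularity=0.9,
                               eccentricity=0.5, foci_distance=1.0,
                               loop_length=5.0, max_curvature=1.0,
                               normalized_curvature=0.5)
            for p in perimeters
        ]

    def test_hand_arithmetic(self):
        stats = population_stats(self._records([10.0, 20.0]))
        per = next(s for s in stats if s.parameter == "perimeter")
        assert per.mean == pytest.approx(15.0)
        assert per.sd == pytest.approx(7.0711, abs=1e-4)
        assert per.sem == pytest.approx(5.0)
        assert per.n == 2

    def test_duplication_shrinks_sem(self):
        base = self._records([8.0, 11.0, 14.0, 17.0, 23.0])
        k = 16
        small = population_stats(base)
        big = population_stats(base * k)
        s0 = next(s for s in small if s.parameter == "perimeter")
        s1 = next(s for s in big if s.parameter == "perimeter")
        assert s1.mean == pytest.approx(s0.mean)
        # SEM shrinks by sqrt(k) up to the (n-1) correction: the duplicated
        # sample's ddof=1 SD is sqrt((n-1)/n * nk/(nk-1)) times the original
        n = len(base)
        correction = math.sqrt((n - 1) / n * (n * k) / (n * k - 1))
        assert s1.sem == pytest.approx(correction * s0.sem / math.sqrt(k), rel=1e-9)

    def test_single_record_cell_omitted(self):
        stats = population_stats(self._records([10.0]))
        assert stats == []

    def test_frame_round_trip(self):
        records = self._records([10.0, 20.0])
        frame = records_to_frame(records)
        assert list(frame["perimeter"]) == [10.0, 20.0]
        assert set(frame.columns) >= {"id", "stain", "label", "area"}
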