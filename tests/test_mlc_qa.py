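import math

import numpy as np
import pytest

from linacqa.core_io import PlanarImage, ValidationError
from linacqa.mlc_qa import (
    DLGFit,
    FitError,
    GeometryError,
    SweepingGapSeries,
    _line_intersection,
    analyze_picket_fence,
    analyze_star_shot,
    fit_dynamic_leaf_gap,
    min_enclosing_circle,
    mlc_transmission,
)
from linacqa.synthetic import (
    gen_picket_fence_image,
    gen_star_shot_image,
    gen_sweeping_gap_series,
)


class TestPicketFence:
    def test_nominal_spacing_recovered(self):
        img, _ = gen_picket_fence_image(5, 30.0)
        res = analyze_picket_fence(img, 30.0)
        assert len(res.distances_mm) == 4
        np.testing.assert_allclose(res.distances_mm, 30.0, atol=0.05)
        assert res.max_deviation_mm <= 0.05

    def test_injected_error_recovered(self):
        img, _ = gen_picket_fence_image(5, 30.0,
                                        per_picket_error_mm=[0, 0, -0.5, 0, 0])
        res = analyze_picket_fence(img, 30.0)
        assert res.max_deviation_mm == pytest.approx(0.5, abs=0.05)

    def test_fwhm_recovered(self):
        img, _ = gen_picket_fence_image(5, 30.0, picket_fwhm_mm=2.2)
        res = analyze_picket_fence(img, 30.0)
        np.testing.assert_allclose(res.fwhm_mm, 2.2, atol=0.1)

    def test_translation_equivariance(self):
        img, _ = gen_picket_fence_image(5, 30.0)
        k = 7
        rolled = PlanarImage(
            pixels=np.roll(img.pixels, k, axis=1),
            pixel_pitch_mm=img.pixel_pitch_mm,
            source_detector_distance_mm=img.source_detector_distance_mm,
            source_axis_distance_mm=img.source_axis_distance_mm,
        )
        a = analyze_picket_fence(img, 30.0)
        b = analyze_picket_fence(rolled, 30.0)
        shift = k * img.pitch_iso_mm
        np.testing.assert_allclose(
            np.array(b.positions_mm) - np.array(a.positions_mm), shift, atol=1e-3
        )

    def test_too_few_pickets_raises(self):
        img, _ = gen_picket_fence_image(1, 30.0)
        with pytest.raises(Exception):
            analyze_picket_fence(img, 30.0)


def _oracle_circle_bruteforce(points):
    """O(n^3) oracle: try every 2-point and 3-point circle, keep the smallest
    that encloses all points."""
    pts = [tuple(map(float, p)) for p in points]
    best = None

    def contains_all(c, r):
        return all(math.dist(c, p) <= r + 1e-9 for p in pts)

    n = len(pts)
    for i in range(n):
        for j in range(i + 1, n):
            c = ((pts[i][0] + pts[j][0]) / 2, (pts[i][1] + pts[j][1]) / 2)
            r = math.dist(pts[i], pts[j]) / 2
            if contains_all(c, r) and (best is None or r < best[1]):
                best = (c, r)
            for k in range(j + 1, n):
                ax, ay = pts[i]
                bx, by = pts[j]
                cx, cy = pts[k]
                d = 2 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
                if abs(d) < 1e-12:
                    continue
                ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay)
                      + (cx**2 + cy**2) * (ay - by)) / d
                uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx)
                      + (cx**2 + cy**2) * (bx - ax)) / d
                r = math.dist((ux, uy), pts[i])
                if contains_all((ux, uy), r) and (best is None or r < best[1]):
                    best = ((ux, uy), r)
    if best is None:  # all points coincident
        return pts[0], 0.0
    return best


def _true_lines(manifest):
    lines = []
    cx, cy = manifest.params["center_mm"]
    for a, off in zip(manifest.params["spoke_angles_deg"],
                      manifest.params["per_spoke_offset_mm"]):
        t = math.radians(a)
        n = (-math.sin(t), math.cos(t))
        lines.append((t, n[0] * cx + n[1] * cy + off))
    return lines


def _oracle_star(manifest):
    lines = _true_lines(manifest)
    inter = []
    for i in range(len(lines)):
        for j in range(i + 1, len(lines)):
            p = _line_intersection(lines[i][0], lines[i][1],
                                   lines[j][0], lines[j][1])
            if p is not None:
                inter.append(p)
    return _oracle_circle_bruteforce(inter)


class TestStarShot:
    def test_concurrent_spokes_tiny_radius(self):
        img, _ = gen_star_shot_image(3)
        res = analyze_star_shot(img)
        assert res.circle_radius_mm < 0.05

    def test_offset_center_recovered(self):
        img, man = gen_star_shot_image(4, center_offset=(0.4, -0.3))
        res = analyze_star_shot(img)
        assert res.circle_center.x == pytest.approx(0.4, abs=0.1)
        assert res.circle_center.y == pytest.approx(-0.3, abs=0.1)

    def test_tangent_circle_vs_geometric_oracle(self):
        img, man = gen_star_shot_image(
            3, per_spoke_offset_mm=[0.6, -0.6, 0.6])
        res = analyze_star_shot(img)
        _, oracle_radius = _oracle_star(man)
        assert res.circle_radius_mm == pytest.approx(oracle_radius, abs=0.1)

    def test_mixed_offsets_vs_oracle(self):
        img, man = gen_star_shot_image(
            5, per_spoke_offset_mm=[0.3, -0.2, 0.25, -0.3, 0.1])
        res = analyze_star_shot(img)
        (ocx, ocy), orad = _oracle_star(man)
        assert res.circle_radius_mm == pytest.approx(orad, abs=0.1)

    def test_intersections_inside_circle(self):
        img, _ = gen_star_shot_image(5, center_offset=(0.2, 0.1))
        res = analyze_star_shot(img)
        c = (res.circle_center.x, res.circle_center.y)
        for p in res.intersections:
            assert math.dist(c, p) <= res.circle_radius_mm + 1e-6

    def test_parallel_slits_raise(self):
        # two parallel dark slits rendered directly
        x = np.linspace(-30, 30, 200)
        X, Y = np.meshgrid(x, x)
        pixels = 1.0 - 0.8 * (np.exp(-((Y - 8) ** 2) / 2) + np.exp(-((Y + 8) ** 2) / 2))
        img = PlanarImage(pixels=np.clip(pixels, 0, None), pixel_pitch_mm=0.45,
                          source_detector_distance_mm=1500.0)
        with pytest.raises(GeometryError):
            analyze_star_shot(img)


class TestMinEnclosingCircle:
    @pytest.mark.parametrize("n", [2, 3, 5, 8, 12])
    def test_matches_bruteforce_oracle(self, n, rng):
        for trial in range(20):
            pts = rng.normal(0, 5, (n, 2))
            (cx, cy), r = min_enclosing_circle(pts)
            (ox, oy), orad = _oracle_circle_bruteforce(pts)
            assert r == pytest.approx(orad, abs=1e-9)
            assert math.dist((cx, cy), (ox, oy)) < 1e-7

    def test_collinear_points(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        (cx, cy), r = min_enclosing_circle(pts)
        assert (cx, cy) == pytest.approx((1.0, 0.0))
        assert r == pytest.approx(1.0)


class TestTransmission:
    def test_measured_value_passes(self):
        rep = mlc_transmission(1.17, 100.0)
        assert rep["transmission_pct"] == pytest.approx(1.17)
        assert rep["pass"]

    def test_zero(self):
        assert mlc_transmission(0.0, 100.0)["transmission_pct"] == 0.0

    def test_above_tolerance_fails(self):
        rep = mlc_transmission(2.5, 100.0)
        assert rep["transmission_pct"] == pytest.approx(2.5)
        assert not rep["pass"]

    def test_zero_open_dose_rejected(self):
        with pytest.raises(ValidationError):
            mlc_transmission(1.0, 0.0)


class TestDynamicLeafGap:
    def test_noise_free_worked_example(self):
        series, _ = gen_sweeping_gap_series(0.02, 0.36, 0.126)
        fit = fit_dynamic_leaf_gap(series)
        assert fit.x_intercept_mm == pytest.approx(-0.72, abs=1e-10)
        assert fit.delta_mm == pytest.approx(0.36, abs=1e-10)
        assert fit.residual_rms_gy < 1e-12

    def test_zero_delta(self):
        series, _ = gen_sweeping_gap_series(0.02, 0.0, 0.126)
        assert fit_dynamic_leaf_gap(series).delta_mm == pytest.approx(0.0, abs=1e-10)

    def test_noisy_recovery_50_seeds(self):
        deltas = []
        for seed in range(50):
            series, _ = gen_sweeping_gap_series(
                0.02, 0.36, 0.126, noise_sigma=0.002, seed=seed)
            deltas.append(fit_dynamic_leaf_gap(series).delta_mm)
        assert np.mean(deltas) == pytest.approx(0.36, abs=0.02)

    def test_offset_invariance(self):
        series, _ = gen_sweeping_gap_series(0.02, 0.36, 0.126)
        shifted = SweepingGapSeries(
            gaps_mm=series.gaps_mm,
            doses_gy=series.doses_gy + 0.5,
            dleak_gy=series.dleak_gy + 0.5,
        )
        a, b = fit_dynamic_leaf_gap(series), fit_dynamic_leaf_gap(shifted)
        assert a.delta_mm == pytest.approx(b.delta_mm, abs=1e-12)

    def test_negative_slope_rejected(self):
        series = SweepingGapSeries(
            gaps_mm=np.array([1.0, 5.0, 10.0]),
            doses_gy=np.array([1.0, 0.9, 0.8]),
            dleak_gy=0.0,
        )
        with pytest.raises(FitError):
            fit_dynamic_leaf_gap(series)

    def test_invariants(self):
        with pytest.raises(ValidationError):
            SweepingGapSeries(gaps_mm=np.array([5.0, 1.0]),
                              doses_gy=np.array([1.0, 2.0]), dleak_gy=0.0)
        with pytest.raises(ValidationError):
            SweepingGapSeries(gaps_mm=np.array([1.0, 5.0]),
                              doses_gy=np.array([0.05, 2.0]), dleak_gy=0.1)
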