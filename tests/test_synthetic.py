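import json

import numpy as np
import pytest

from linacqa import synthetic
from linacqa.synthetic import (
    FieldFluenceModel,
    GenerationError,
    GroundTruthManifest,
    disc_average,
    gen_bb_aperture_image,
    gen_detector_readings,
    gen_dose_planes,
    gen_line_pair_image,
    gen_picket_fence_image,
    gen_shift_samples,
    gen_star_shot_image,
    gen_sweeping_gap_series,
)


class TestManifest:
    def test_json_round_trip(self):
        m = GroundTruthManifest("g", 7, {"a": [1.0, 2.0], "b": "x"})
        back = GroundTruthManifest.from_json(m.to_json())
        assert back == m


class TestBBAperture:
    def test_centered_bb_is_symmetric(self):
        img, _ = gen_bb_aperture_image((0.0, 0.0), {"square": (15.0, 15.0)})
        # noise-free centered render must be exactly mirror-symmetric
        np.testing.assert_allclose(img.pixels, img.pixels[::-1, :], atol=1e-12)
        np.testing.assert_allclose(img.pixels, img.pixels[:, ::-1], atol=1e-12)

    def test_manifest_echoes_offset(self):
        _, man = gen_bb_aperture_image((0.35, 0.325), {"square": (15.0, 15.0)})
        assert man.params["bb_offset_mm"] == [0.35, 0.325]

    def test_seeded_determinism(self):
        a, _ = gen_bb_aperture_image((0.2, -0.1), {"cone": 12.5},
                                     noise_sigma=0.02, seed=99)
        b, _ = gen_bb_aperture_image((0.2, -0.1), {"cone": 12.5},
                                     noise_sigma=0.02, seed=99)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_bb_overlapping_edge_rejected(self):
        with pytest.raises(GenerationError):
            gen_bb_aperture_image((6.0, 0.0), {"square": (15.0, 15.0)})
        with pytest.raises(GenerationError):
            gen_bb_aperture_image((4.0, 0.0), {"cone": 12.5})


class TestPicketFence:
    def test_nominal_gaps_in_manifest(self):
        _, man = gen_picket_fence_image(5, 30.0)
        np.testing.assert_allclose(man.params["gaps_mm"], [30.0] * 4)

    def test_single_picket(self):
        _, man = gen_picket_fence_image(1, 30.0)
        assert len(man.params["positions_mm"]) == 1
        assert man.params["gaps_mm"] == []

    def test_injected_error_echoed(self):
        _, man = gen_picket_fence_image(5, 30.0,
                                        per_picket_error_mm=[0, 0, 0.5, 0, 0])
        assert man.params["max_deviation_mm"] == pytest.approx(0.5)

    def test_spacing_below_width_rejected(self):
        with pytest.raises(GenerationError):
            gen_picket_fence_image(3, 2.0, picket_fwhm_mm=2.2)


class TestStarShot:
    def test_centered_manifest(self):
        _, man = gen_star_shot_image(3)
        assert man.params["center_mm"] == [0.0, 0.0]

    def test_offset_echoed(self):
        _, man = gen_star_shot_image(3, center_offset=(0.4, -0.3))
        assert man.params["center_mm"] == [0.4, -0.3]

    def test_seeded_determinism(self):
        a, _ = gen_star_shot_image(4, noise_sigma=0.02, seed=5)
        b, _ = gen_star_shot_image(4, noise_sigma=0.02, seed=5)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_duplicate_angles_rejected(self):
        with pytest.raises(GenerationError):
            gen_star_shot_image(2, spoke_angles_deg=[30.0, 210.0])


class TestSweepingGap:
    def test_direct_model_evaluation(self):
        series, _ = gen_sweeping_gap_series(0.02, 0.36, 0.126, gaps_mm=[1.0, 5.0])
        # D = Dleak + b*(gap + 2*delta) = 0.126 + 0.02*1.72
        assert series.doses_gy[0] == pytest.approx(0.1604, abs=1e-12)

    def test_zero_delta_proportional(self):
        series, _ = gen_sweeping_gap_series(0.05, 0.0, 0.1,
                                            gaps_mm=[2.0, 4.0, 8.0])
        net = series.doses_gy - series.dleak_gy
        np.testing.assert_allclose(net / series.gaps_mm, 0.05)

    def test_noise_free_is_deterministic(self):
        a, _ = gen_sweeping_gap_series(0.02, 0.36, 0.126)
        b, _ = gen_sweeping_gap_series(0.02, 0.36, 0.126, seed=123)
        np.testing.assert_array_equal(a.doses_gy, b.doses_gy)

    def test_single_gap_rejected(self):
        with pytest.raises(GenerationError):
            gen_sweeping_gap_series(0.02, 0.36, 0.126, gaps_mm=[5.0])


class TestDetectorReadings:
    def test_zero_aperture_is_point_dose(self):
        model = FieldFluenceModel(shoulder_sigma_mm=2.5)
        point = float(model(np.zeros(1), np.zeros(1), 20.0)[0])
        assert disc_average(model, 20.0, 0.0) == pytest.approx(point)

    def test_flat_top_plateau(self):
        model = FieldFluenceModel(shoulder_sigma_mm=1.0)
        # 100 mm field, 2 mm aperture: fully on the plateau
        assert disc_average(model, 100.0, 2.0) == pytest.approx(1.0, abs=1e-9)

    def test_volume_averaging_depresses_reading(self):
        # 6 mm aperture on a 5 mm flat-top with Gaussian shoulders:
        # numeric disc-average oracle on a polar grid
        model = FieldFluenceModel(shoulder_sigma_mm=2.0)
        reading = disc_average(model, 5.0, 6.0, n_grid=501)
        plateau = float(model(np.zeros(1), np.zeros(1), 5.0)[0])
        assert reading < plateau
        # independent oracle: radial quadrature of the disc mean
        r = np.linspace(0, 3.0, 2000)
        th = np.linspace(0, 2 * np.pi, 720, endpoint=False)
        R, T = np.meshgrid(r, th)
        vals = model(R * np.cos(T), R * np.sin(T), 5.0)
        oracle = float((vals * R).sum() / R.sum())
        assert reading == pytest.approx(oracle, rel=1e-3)

    def test_aperture_warning_flag(self):
        tables, man = gen_detector_readings(None, [20.0], [5.0, 100.0])
        assert any("aperture exceeds" in w for w in man.params["warnings"])


class TestDosePlanes:
    def test_zero_perturbation_identical(self):
        ref, ev, _ = gen_dose_planes()
        np.testing.assert_array_equal(ref.dose, ev.dose)

    def test_uniform_scale_echoed(self):
        ref, ev, man = gen_dose_planes(perturbation={"scale_pct": 3.0})
        mask = ref.dose > 1.0
        np.testing.assert_allclose(ev.dose[mask] / ref.dose[mask], 1.03)
        assert man.params["scale_pct"] == 3.0

    def test_seeded_noise_reproducible(self):
        _, a, _ = gen_dose_planes(perturbation={"noise_sigma": 2.0}, seed=11)
        _, b, _ = gen_dose_planes(perturbation={"noise_sigma": 2.0}, seed=11)
        np.testing.assert_array_equal(a.dose, b.dose)

    def test_bad_pitch_rejected(self):
        with pytest.raises(GenerationError):
            gen_dose_planes(grid_pitch_mm=0.0)


class TestShiftSamples:
    def test_zero_sigma_all_identity(self):
        shifts, _ = gen_shift_samples(0.0, 0.0, 5, seed=0)
        assert all(s.translation.tolist() == [0, 0, 0] for s in shifts)
        assert all(s.rotation_deg.tolist() == [0, 0, 0] for s in shifts)

    def test_count(self):
        shifts, man = gen_shift_samples(1.0, 0.5, 711, seed=3)
        assert len(shifts) == 711
        assert man.params["n"] == 711

    def test_seeded_determinism(self):
        a, _ = gen_shift_samples(1.0, 0.5, 10, seed=8)
        b, _ = gen_shift_samples(1.0, 0.5, 10, seed=8)
        assert a == b


class TestLinePairs:
    def test_rois_cover_all_groups(self):
        freqs = [0.5, 1.0, 2.0]
        img, rois, man = gen_line_pair_image(freqs)
        assert [f for _, f in rois] == freqs
        assert set(man.params["oracle_modulation"]) == {"0.5", "1.0", "2.0"}

    def test_oracle_modulation_decreases_with_frequency(self):
        _, _, man = gen_line_pair_image([0.5, 1.0, 2.0, 4.0], blur_sigma_mm=0.3)
        mods = [man.params["oracle_modulation"][k] for k in ["0.5", "1.0", "2.0", "4.0"]]
        assert mods == sorted(mods, reverse=True)


def test_generators_are_pure_functions_of_params_and_seed():
    for make in [
        lambda: gen_bb_aperture_image((0.1, 0.2), {"square": (15, 15)},
                                      noise_sigma=0.01, seed=4)[0].pixels,
        lambda: gen_picket_fence_image(5, 30.0, noise_sigma=0.01, seed=4)[0].pixels,
        lambda: gen_star_shot_image(3, noise_sigma=0.01, seed=4)[0].pixels,
        lambda: gen_dose_planes(perturbation={"noise_sigma": 1.0}, seed=4)[1].dose,
    ]:
        np.testing.assert_array_equal(make(), make())
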