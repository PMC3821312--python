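"""Confocal forward model: retardation, depolarization, crossed intensities, rendering."""

import numpy as np
import pytest

from polbiref import (
    FiberScene,
    IlluminationState,
    InstrumentConfig,
    SVRConfig,
    crossed_intensity,
    depth_dop,
    render_depth_series,
    render_image,
    retardation,
)


def closed_form(mode, theta, psi, d, p, b=0.0, i0=1.0):
    """Independent trigonometric oracle for the crossed-detected intensity."""
    if mode == "linear":
        return i0 * p * np.sin(np.radians(2 * (theta - psi))) ** 2 * np.sin(d / 2) ** 2 + b
    if mode == "circular":
        return i0 * p * np.sin(d / 2) ** 2 + b
    return 0.5 * i0 * p * np.sin(d / 2) ** 2 + b  # radial pupil average


class TestRetardation:
    def test_zero_path(self):
        assert retardation(0.0) == 0.0

    def test_half_wave_path_from_cortex_constants(self):
        # delta * x = lambda / 2: x = 0.415 / 0.007 um for the hair cortex
        x = 0.415 / 0.007
        assert retardation(x, 0.007, 0.83) == pytest.approx(np.pi, rel=1e-12)

    def test_linear_in_path_and_double_pass(self):
        assert retardation(20.0) == pytest.approx(2 * retardation(10.0))
        assert retardation(10.0, double_pass=True) == pytest.approx(2 * retardation(10.0))

    def test_negative_path_rejected(self):
        with pytest.raises(ValueError):
            retardation(-1.0)


class TestDepthDop:
    def test_limits_and_monotonicity(self):
        assert depth_dop(0.0, 100.0) == 1.0
        assert depth_dop(100.0, 100.0) == pytest.approx(np.exp(-1))
        x = np.linspace(0, 500, 50)
        p = depth_dop(x, 100.0)
        assert np.all(np.diff(p) < 0)
        assert depth_dop(1e6, 100.0) < 1e-300 or depth_dop(1e6, 100.0) == 0.0

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            depth_dop(1.0, 0.0)
        with pytest.raises(ValueError):
            depth_dop(-1.0, 10.0)


class TestCrossedIntensity:
    def test_mueller_chain_matches_closed_forms(self):
        """1000 random parameter tuples, all three modes, tolerance 1e-10."""
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            theta, psi = rng.uniform(0, 360, 2)
            d = rng.uniform(0, 2 * np.pi)
            p = rng.uniform(0, 1)
            b = rng.uniform(0, 0.2)
            lin = crossed_intensity(IlluminationState("linear", angle=theta), psi, d, p, b)
            assert lin == pytest.approx(closed_form("linear", theta, psi, d, p, b), abs=1e-10)
            circ = crossed_intensity(IlluminationState("circular"), psi, d, p, b)
            assert circ == pytest.approx(closed_form("circular", 0, psi, d, p, b), abs=1e-10)
            rad = crossed_intensity(IlluminationState("radial"), psi, d, p, b)
            assert rad == pytest.approx(closed_form("radial", 0, psi, d, p, b), abs=1e-10)

    def test_linear_minimum_aligned_and_crossed(self):
        for dtheta in (0.0, 90.0):
            i = crossed_intensity(IlluminationState("linear", angle=10.0 + dtheta),
                                  10.0, np.pi, 1.0, b=0.07)
            assert i == pytest.approx(0.07, abs=1e-12)

    def test_linear_maximum_at_45(self):
        angles = np.linspace(0, 90, 91)
        vals = [crossed_intensity(IlluminationState("linear", angle=a), 0.0, np.pi, 1.0)
                for a in angles]
        assert np.argmax(vals) == 45
        assert vals[45] == pytest.approx(1.0)

    def test_linear_period_90_in_relative_angle(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            th, ps, d, p = rng.uniform(0, 360), rng.uniform(0, 360), rng.uniform(0, 6), rng.uniform(0, 1)
            a = crossed_intensity(IlluminationState("linear", angle=th), ps, d, p)
            b = crossed_intensity(IlluminationState("linear", angle=th + 90), ps, d, p)
            assert a == pytest.approx(b, abs=1e-10)

    def test_circular_orientation_independent(self):
        d = 1.3
        i1 = crossed_intensity(IlluminationState("circular"), 0.0, d, 0.8)
        i2 = crossed_intensity(IlluminationState("circular"), 45.0, d, 0.8)
        assert i1 == pytest.approx(i2, abs=1e-12)

    def test_circular_handedness_sign_irrelevant(self):
        for h in (+1, -1):
            i = crossed_intensity(IlluminationState("circular", handedness=h), 33.0, 2.1, 0.9)
            assert i == pytest.approx(closed_form("circular", 0, 33.0, 2.1, 0.9), abs=1e-10)

    def test_radial_invariance_ideal_and_sectored(self):
        d, p = 1.7, 0.6
        ideal = [crossed_intensity(IlluminationState("radial"), psi, d, p)
                 for psi in (0.0, 13.0, 45.0, 77.7)]
        assert np.ptp(ideal) < 1e-12
        svr = IlluminationState("radial", svr=SVRConfig())
        sectored = [crossed_intensity(svr, psi, d, p) for psi in (0.0, 13.0, 45.0, 77.7)]
        assert np.ptp(sectored) / np.mean(sectored) < 0.005

    def test_depolarization_limit_modes_converge(self):
        """As p -> 0 every illumination mode collapses to the background."""
        d, b = 2.0, 0.03
        vals = [
            crossed_intensity(IlluminationState("linear", angle=45.0), 0.0, d, 1e-6, b),
            crossed_intensity(IlluminationState("circular"), 0.0, d, 1e-6, b),
            crossed_intensity(IlluminationState("radial"), 0.0, d, 1e-6, b),
        ]
        assert np.allclose(vals, b, atol=1e-5)

    def test_invalid_dop_rejected(self):
        with pytest.raises(ValueError):
            crossed_intensity(IlluminationState("circular"), 0.0, 1.0, 1.5)


class TestFiberScene:
    def test_birefringence_derived_from_indices(self):
        assert FiberScene().birefringence == pytest.approx(1.548 - 1.541)

    def test_inconsistent_birefringence_rejected(self):
        with pytest.raises(ValueError):
            FiberScene(birefringence=0.02)


class TestRenderImage:
    instrument = InstrumentConfig(field_of_view=(150.0, 150.0), image_pixels=(120, 120))

    def test_no_birefringence_no_contrast(self):
        scene = FiberScene(n_o=1.5, n_e=1.5, background_level=0.04, focus_depth=30.0)
        img = render_image(scene, IlluminationState("linear", angle=45.0), self.instrument)
        assert np.allclose(img.intensity, 0.04, atol=1e-12)

    def test_frame_invariance_under_joint_rotation(self):
        """Rotating fiber and polarization together preserves image statistics."""
        scene0 = FiberScene(fiber_axis_angle=0.0, background_level=0.01, focus_depth=20.0)
        scene90 = FiberScene(fiber_axis_angle=90.0, background_level=0.01, focus_depth=20.0)
        img0 = render_image(scene0, IlluminationState("linear", angle=45.0), self.instrument)
        img90 = render_image(scene90, IlluminationState("linear", angle=135.0), self.instrument)
        # square grid: the two footprints are congruent under a quarter turn
        assert np.sort(img0.intensity.ravel()) == pytest.approx(
            np.sort(img90.intensity.ravel()), abs=1e-12)

    def test_45_brighter_than_aligned(self):
        scene = FiberScene(background_level=0.02, focus_depth=25.0)
        at45 = render_image(scene, IlluminationState("linear", angle=45.0), self.instrument)
        at0 = render_image(scene, IlluminationState("linear", angle=0.0), self.instrument)
        from polbiref.confocal_model import fiber_footprint
        _, _, inside = fiber_footprint(scene, self.instrument)
        assert at45.intensity[inside].mean() > at0.intensity[inside].mean()

    def test_power_scales_frame(self):
        scene = FiberScene(background_level=0.02, focus_depth=25.0)
        bright = InstrumentConfig(field_of_view=(150.0, 150.0), image_pixels=(120, 120),
                                  illumination_power=2.0)
        img1 = render_image(scene, IlluminationState("circular"), self.instrument)
        img2 = render_image(scene, IlluminationState("circular"), bright)
        assert img2.intensity == pytest.approx(2 * img1.intensity)

    def test_empty_footprint_warns(self):
        # fiber thinner than the pixel spacing: no pixel centre falls on it
        small = InstrumentConfig(field_of_view=(30.0, 30.0), image_pixels=(16, 16))
        scene = FiberScene(fiber_diameter=0.5, focus_depth=5.0)
        with pytest.warns(UserWarning, match="footprint"):
            render_image(scene, IlluminationState("circular"), small)


class TestRenderDepthSeries:
    def test_zero_depth_is_background(self):
        scene = FiberScene(background_level=0.03)
        inst = InstrumentConfig(field_of_view=(150.0, 150.0), image_pixels=(100, 100))
        series = render_depth_series(scene, IlluminationState("linear", angle=45.0),
                                     inst, [0.0])
        assert np.allclose(series[0].intensity, 0.03, atol=1e-12)

    def test_orientations_converge_at_depth_with_strong_depolarization(self):
        scene = FiberScene(background_level=0.05, depolarization_length=8.0)
        inst = InstrumentConfig(field_of_view=(150.0, 150.0), image_pixels=(100, 100))
        depths = [10.0, 70.0]
        from polbiref.synthetic_data import fixture_masks
        # central band of the fiber, where the chord exceeds the probed depths
        inside, _ = fixture_masks(scene, inst)
        sep = []
        for depth in depths:
            ims = {}
            for theta in (0.0, 45.0):
                scene_d = FiberScene(background_level=0.05, depolarization_length=8.0,
                                     focus_depth=depth)
                img = render_image(scene_d, IlluminationState("linear", angle=theta), inst)
                ims[theta] = img.intensity[inside].mean()
            sep.append(abs(ims[45.0] - ims[0.0]))
        assert sep[1] < sep[0] * 0.1
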