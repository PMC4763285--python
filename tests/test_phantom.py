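"""Phantom simulator: growth law, scene rendering, frame capture, time-lapse."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage.registration import phase_cross_correlation

from microcolony.geometry import IlluminationSource, ScanSchedule, SensorSpec, compute_shadow_shift
from microcolony.phantom import (
    ColonyOptics,
    ColonySeed,
    GrowthModel,
    NoiseParams,
    PlatePhantom,
    capture_frame,
    ground_truth_table,
    render_scene,
    simulate_timelapse,
)


class TestGrowthModel:
    def test_linear_expansion_after_lag(self):
        g = GrowthModel(lag_time_min=240.0, radial_rate_um_per_min=0.1, seed_diameter_um=1.0)
        assert g.diameter_um(0.0) == 1.0
        assert g.diameter_um(240.0) == 1.0
        assert g.diameter_um(360.0) == pytest.approx(25.0)  # 1 + 2·0.1·120

    @given(
        t0=st.floats(0, 400),
        v=st.floats(0.01, 0.5),
        t1=st.floats(0, 800),
        t2=st.floats(0, 800),
    )
    @settings(max_examples=100, deadline=None)
    def test_diameter_is_non_decreasing(self, t0, v, t1, t2):
        g = GrowthModel(lag_time_min=t0, radial_rate_um_per_min=v)
        lo, hi = sorted((t1, t2))
        assert g.diameter_um(hi) >= g.diameter_um(lo)


def _measured_diameter(scene, optics: ColonyOptics) -> float:
    """Equivalent diameter of the half-depth dark area of a scene."""
    half = (1.0 + optics.center_transmission) / 2.0
    area_um2 = float((scene.transmission < half).sum()) * scene.pitch_um**2
    return 2.0 * np.sqrt(area_um2 / np.pi)


class TestRenderScene:
    def test_uniform_before_lag(self, small_sensor):
        g = GrowthModel(lag_time_min=240.0, radial_rate_um_per_min=0.1)
        ph = PlatePhantom(small_sensor, (ColonySeed(100.0, 100.0, g),), z_um=5.0)
        scene = render_scene(ph, 120.0, supersample=4)
        assert np.array_equal(scene.transmission, np.ones_like(scene.transmission))

    def test_drawn_diameter_follows_growth_law(self, small_sensor):
        g = GrowthModel(lag_time_min=240.0, radial_rate_um_per_min=0.1, seed_diameter_um=1.0)
        ph = PlatePhantom(small_sensor, (ColonySeed(105.0, 105.0, g),), z_um=5.0)
        scene = render_scene(ph, 360.0, supersample=8)
        assert _measured_diameter(scene, ph.optics) == pytest.approx(25.0, abs=0.3)

    def test_overlapping_colonies_form_one_dark_component(self, small_sensor):
        from scipy import ndimage

        g = GrowthModel(lag_time_min=0.0, radial_rate_um_per_min=0.1, seed_diameter_um=1.0)
        ph = PlatePhantom(
            small_sensor,
            (ColonySeed(90.0, 105.0, g), ColonySeed(120.0, 105.0, g)),  # 30 μm apart
            z_um=5.0,
        )
        scene = render_scene(ph, 195.0, supersample=4)  # d = 40 μm
        dark = scene.transmission < (1.0 + ph.optics.center_transmission) / 2.0
        _, n_components = ndimage.label(dark)
        assert n_components == 1

    def test_transmission_bounds(self, single_colony_phantom):
        scene = render_scene(single_colony_phantom, 300.0, supersample=4)
        assert scene.transmission.min() >= 0.0
        assert scene.transmission.max() <= 1.0


class TestCaptureFrame:
    def test_empty_scene_noiseless_is_full_scale(self, small_sensor, onaxis):
        ph = PlatePhantom(small_sensor, (), z_um=5.0)
        scene = render_scene(ph, 0.0, supersample=2)
        frame = capture_frame(scene, onaxis, 5.0, small_sensor, noise=NoiseParams.noiseless())
        assert frame.dtype == np.uint8
        assert np.array_equal(frame, np.full_like(frame, 255))

    def test_opaque_disk_shadow_area(self, small_sensor, onaxis):
        # opaque 50-μm disk → (π/4)·50²/2.2² ≈ 405 LR px below half background
        disk = GrowthModel(lag_time_min=0.0, radial_rate_um_per_min=0.0, seed_diameter_um=50.0)
        ph = PlatePhantom(
            small_sensor,
            (ColonySeed(105.6, 105.6, disk),),
            z_um=5.0,
            optics=ColonyOptics(center_transmission=0.0),
        )
        scene = render_scene(ph, 0.0, supersample=4)
        frame = capture_frame(
            scene, onaxis, 5.0, small_sensor, noise=NoiseParams.noiseless(), blur_sigma_um=0.0
        )
        n_dark = int((frame < 128).sum())
        assert n_dark == pytest.approx(405, rel=0.10)

    def test_measured_shift_matches_geometry(self, small_sensor, single_colony_phantom):
        plus = IlluminationSource(offset_mm=(15.0, 0.0), height_mm=80.0)
        minus = IlluminationSource(offset_mm=(-15.0, 0.0), height_mm=80.0)
        ph = PlatePhantom(
            small_sensor, single_colony_phantom.colonies, z_um=50.0, seed=single_colony_phantom.seed
        )
        scene = render_scene(ph, 300.0, supersample=8)
        f1 = capture_frame(scene, plus, 50.0, small_sensor, noise=NoiseParams.noiseless()).astype(float)
        f2 = capture_frame(scene, minus, 50.0, small_sensor, noise=NoiseParams.noiseless()).astype(float)
        measured, _, _ = phase_cross_correlation(f1, f2, upsample_factor=500)
        expected = compute_shadow_shift(plus, 50.0, small_sensor)
        assert measured[1] == pytest.approx(2 * expected.dx, abs=0.05)
        assert measured[0] == pytest.approx(2 * expected.dy, abs=0.05)

    def test_absorbed_signal_invariant_under_shift(self, small_sensor, single_colony_phantom, onaxis):
        """Total absorbed signal must not depend on the illumination angle."""
        tilted = IlluminationSource(offset_mm=(3.0, -2.0), height_mm=80.0)
        scene = render_scene(single_colony_phantom, 300.0, supersample=4)
        quiet = NoiseParams.noiseless(flat_field_amplitude=0.0, bit_depth=16)
        f_on = capture_frame(scene, onaxis, 5.0, small_sensor, noise=quiet).astype(float)
        f_tilt = capture_frame(scene, tilted, 5.0, small_sensor, noise=quiet).astype(float)
        full = float(quiet.full_scale)
        absorbed_on = (full - f_on).sum()
        absorbed_tilt = (full - f_tilt).sum()
        assert absorbed_tilt == pytest.approx(absorbed_on, rel=1e-3)

    def test_mismatched_grid_rejected(self, small_sensor, onaxis):
        other = SensorSpec(2.2, 32, 32)
        ph = PlatePhantom(other, (), z_um=5.0)
        scene = render_scene(ph, 0.0, supersample=2)
        with pytest.raises(ValueError, match="does not match"):
            capture_frame(scene, onaxis, 5.0, small_sensor, noise=NoiseParams.noiseless())


class TestSimulateTimelapse:
    def test_single_timepoint_when_start_equals_end(self, single_colony_phantom, onaxis_schedule):
        stacks, truth = simulate_timelapse(
            single_colony_phantom, onaxis_schedule, 100.0, 100.0, supersample=2
        )
        assert len(stacks) == 1
        assert stacks[0].t_min == 100.0

    def test_twelve_hours_at_twenty_minutes_gives_37_timepoints(
        self, single_colony_phantom, onaxis_schedule
    ):
        stacks, _ = simulate_timelapse(single_colony_phantom, onaxis_schedule, 0.0, 720.0, 20.0, supersample=2)
        assert len(stacks) == 37

    def test_fixed_seed_reproduces_bit_identical_frames(self, single_colony_phantom, onaxis_schedule):
        s1, t1 = simulate_timelapse(single_colony_phantom, onaxis_schedule, 280.0, 320.0, 20.0, supersample=2)
        s2, t2 = simulate_timelapse(single_colony_phantom, onaxis_schedule, 280.0, 320.0, 20.0, supersample=2)
        for a, b in zip(s1, s2):
            assert np.array_equal(a.frames, b.frames)
        assert t1.equals(t2)

    def test_nonpositive_interval_rejected(self, single_colony_phantom, onaxis_schedule):
        with pytest.raises(ValueError):
            simulate_timelapse(single_colony_phantom, onaxis_schedule, 0.0, 100.0, 0.0)


class TestGroundTruth:
    def test_merged_component_count_never_exceeds_seeded(self, small_sensor):
        rng_phantom = PlatePhantom.random(
            small_sensor, n_colonies=4, z_um=5.0, seed=5, min_separation_um=30.0, margin_um=40.0,
            mean_lag_min=100.0, sd_lag_min=20.0,
        )
        truth = ground_truth_table(rng_phantom, [0.0, 200.0, 400.0, 600.0])
        for t, sub in truth.groupby("timepoint_min"):
            visible = sub[sub.true_diameter_um > 0]
            if len(visible):
                assert visible.merged_component_id.nunique() <= len(rng_phantom.colonies)

    def test_density_property(self, small_sensor):
        ph = PlatePhantom.random(small_sensor, n_colonies=3, seed=1, min_separation_um=20.0, margin_um=30.0)
        area_cm2 = small_sensor.fov_mm2 / 100.0
        assert ph.density_cfu_per_cm2 == pytest.approx(3 / area_cm2)

    def test_colony_outside_fov_rejected(self, small_sensor):
        g = GrowthModel(0.0, 0.1)
        with pytest.raises(ValueError, match="outside"):
            PlatePhantom(small_sensor, (ColonySeed(1e6, 0.0, g),), z_um=5.0)
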