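"""Validation studies: simulation experiments that check the pipeline end to end.

Each function runs one self-contained experiment — generate a phantom,
image it, push it through reconstruction/segmentation/tracking, and
measure how well the known ground truth is recovered.  They are used both
by the test suite (which asserts the expected outcomes) and by the
acceptance script (which reports the measured numbers).

All randomness flows through an explicit integer seed.
"""

from __future__ import annotations

import itertools
import math
import warnings
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .geometry import (
    IlluminationSource,
    ScanSchedule,
    SensorSpec,
    compute_shadow_shift,
    design_scan,
    schedule_shifts,
)
from .phantom import (
    ColonyOptics,
    ColonySeed,
    GrowthModel,
    NoiseParams,
    PlatePhantom,
    capture_frame,
    capture_stack,
    render_scene,
)
from .reconstruct import HRImage, autofocus, reconstruct_at, shift_and_add, two_point_dip
from .segment import SegmentationParams, count_colonies, segment
from .tracking import density_scale_bound, fit_growth_rate, link_tracks, mann_whitney_exact

ONAXIS_80 = IlluminationSource(offset_mm=(0.0, 0.0), height_mm=80.0)


# ---------------------------------------------------------------------------
# analytic quantities


def density_bound_microcolony() -> float:
    """Countable-density bound scaled from 1-mm colonies (10 CFU/cm²) to 20 μm."""
    return density_scale_bound(10.0, base_diameter_um=1000.0, target_diameter_um=20.0)


def fov_area_mm2(sensor: SensorSpec | None = None) -> float:
    """Imaging area of the (default) sensor in mm²."""
    return (sensor or SensorSpec()).fov_mm2


# ---------------------------------------------------------------------------
# geometry oracles


def ray_trace_shift(source: IlluminationSource, z_um: float, sensor: SensorSpec) -> tuple[float, float]:
    """Independent shadow-shift oracle: parametric line–plane intersection.

    Traces the ray from the source position through a point at (0, 0, z)
    to the sensor plane z = 0 and returns the displacement of the
    intersection from the point's lateral position, in LR pixels.
    """
    sx = source.offset_mm[0] * 1000.0
    sy = source.offset_mm[1] * 1000.0
    sz = source.height_mm * 1000.0
    px, py, pz = 0.0, 0.0, z_um
    # ray: R(t) = S + t (P − S); solve R_z(t) = 0
    t = sz / (sz - pz)
    ix = sx + t * (px - sx)
    iy = sy + t * (py - sy)
    return ((ix - px) / sensor.pixel_pitch_um, (iy - py) / sensor.pixel_pitch_um)


def shift_model_max_rel_error(seed: int, n_geometries: int = 100) -> float:
    """Worst relative disagreement between the shift model and the ray oracle."""
    rng = np.random.default_rng(seed)
    sensor = SensorSpec()
    worst = 0.0
    for _ in range(n_geometries):
        h_mm = rng.uniform(20.0, 200.0)
        z_um = rng.uniform(1.0, 500.0)
        lx, ly = rng.uniform(-40.0, 40.0, size=2)
        src = IlluminationSource(offset_mm=(float(lx), float(ly)), height_mm=float(h_mm))
        model = compute_shadow_shift(src, z_um, sensor)
        oracle = ray_trace_shift(src, z_um, sensor)
        norm = math.hypot(*oracle)
        if norm == 0:
            continue
        err = math.hypot(model.dx - oracle[0], model.dy - oracle[1]) / norm
        worst = max(worst, err)
    return worst


def frame_mean_equivalence_max_error(seed: int, n_frames: int = 8, size: int = 32) -> float:
    """Degenerate shift-and-add (E=1, zero shifts) vs the arithmetic frame mean."""
    rng = np.random.default_rng(seed)
    frames = rng.uniform(0.0, 255.0, size=(n_frames, size, size))
    zero = [compute_shadow_shift(ONAXIS_80, 0.0, SensorSpec())] * n_frames
    out = shift_and_add(frames, zero, enhancement=1)
    return float(np.abs(out - frames.mean(axis=0)).max())


# ---------------------------------------------------------------------------
# imaging studies


def _two_point_phantom(sensor: SensorSpec, separation_um: float) -> PlatePhantom:
    # pair centred on a pixel boundary: the blind sampling phase for the raw frame
    pitch = sensor.pixel_pitch_um
    cx = (sensor.width_px // 2) * pitch
    cy = (sensor.height_px // 2) * pitch
    dot = GrowthModel(lag_time_min=0.0, radial_rate_um_per_min=0.0, seed_diameter_um=1.6)
    optics = ColonyOptics(center_transmission=0.0, edge_width_um=0.6)
    return PlatePhantom(
        sensor=sensor,
        colonies=(
            ColonySeed(cx - separation_um / 2.0, cy, dot),
            ColonySeed(cx + separation_um / 2.0, cy, dot),
        ),
        z_um=5.0,
        seed=0,
        optics=optics,
    )


def resolution_gain_study(
    seed: int,
    separation_um: float = 4.4,
    enhancement: int = 4,
    grid_n: int = 8,
) -> dict[str, float]:
    """Two-point resolution: HR reconstruction vs a single on-axis LR frame.

    The point pair (separation two LR pixels) straddles a pixel boundary —
    the sampling phase at which a raw frame cannot separate them.  Returns
    the fractional intensity dip between the points in the enhanced
    reconstruction and in the on-axis LR frame; ≥ 0.2 counts as resolved.
    """
    sensor = SensorSpec(pixel_pitch_um=2.2, width_px=48, height_px=48)
    phantom = _two_point_phantom(sensor, separation_um)
    schedule = design_scan(sensor, phantom.z_um, enhancement, grid_n, height_mm=80.0)
    rng = np.random.default_rng(seed)
    scene = render_scene(phantom, 0.0, supersample=2 * enhancement)
    stack = capture_stack(phantom, schedule, 0.0, supersample=2 * enhancement, noise=NoiseParams(), rng=rng, scene=scene)
    hr = reconstruct_at(stack, sensor, phantom.z_um, enhancement)
    lr = capture_frame(scene, ONAXIS_80, phantom.z_um, sensor, noise=NoiseParams(), rng=rng).astype(float)

    pitch = sensor.pixel_pitch_um
    cx = (sensor.width_px // 2) * pitch
    cy = (sensor.height_px // 2) * pitch
    half = separation_um / 2.0
    hp = hr.hr_pitch_um
    hr_dip = two_point_dip(
        hr.data, ((cx - half) / hp - 0.5, cy / hp - 0.5), ((cx + half) / hp - 0.5, cy / hp - 0.5)
    )
    lr_dip = two_point_dip(
        lr, ((cx - half) / pitch - 0.5, cy / pitch - 0.5), ((cx + half) / pitch - 0.5, cy / pitch - 0.5)
    )
    return {"hr_dip": float(hr_dip), "lr_dip": float(lr_dip)}


def count_recovery_study(seed: int, n_colonies: int = 50, n_noise_seeds: int = 5) -> dict:
    """Enumeration of a fully grown phantom on the full-FOV sensor.

    Seeds ``n_colonies`` well-separated colonies on the default
    5.7 mm × 4.3 mm sensor, grows them to 600 min (mean diameter ~73 μm),
    images once noiselessly and ``n_noise_seeds`` times at default noise,
    and counts colonies with the default ≥20 μm rule.
    """
    sensor = SensorSpec()
    phantom = PlatePhantom.random(sensor, n_colonies=n_colonies, z_um=5.0, seed=seed, min_separation_um=150.0)
    schedule = ScanSchedule((ONAXIS_80,))
    scene = render_scene(phantom, 600.0, supersample=2)

    def count_at(noise: NoiseParams, rng) -> int:
        stack = capture_stack(phantom, schedule, 600.0, supersample=2, noise=noise, rng=rng, scene=scene)
        hr = reconstruct_at(stack, sensor, phantom.z_um, enhancement=1)
        return count_colonies(segment(hr))

    noiseless = count_at(NoiseParams.noiseless(flat_field_amplitude=0.05), None)
    noisy = [
        count_at(NoiseParams(), np.random.default_rng(seed * 1000 + k + 1)) for k in range(n_noise_seeds)
    ]
    return {"n_true": n_colonies, "noiseless_count": noiseless, "noisy_counts": noisy}


def sizing_study(seed: int, diameters_um: Sequence[float] = (20.0, 40.0, 80.0), enhancement: int = 4) -> dict:
    """Equivalent-diameter accuracy on disk phantoms at default noise.

    One disk per run, off-grid centre, enhanced reconstruction at the true
    height, default segmentation.  Returns per-diameter absolute errors and
    their mean, in μm.
    """
    sensor = SensorSpec(pixel_pitch_um=2.2, width_px=96, height_px=96)
    schedule = design_scan(sensor, 5.0, enhancement, 8, height_mm=80.0)
    errors = {}
    rng = np.random.default_rng(seed)
    for d in diameters_um:
        cx = (sensor.width_px / 2 + rng.uniform(-0.5, 0.5)) * sensor.pixel_pitch_um
        cy = (sensor.height_px / 2 + rng.uniform(-0.5, 0.5)) * sensor.pixel_pitch_um
        disk = GrowthModel(lag_time_min=0.0, radial_rate_um_per_min=0.0, seed_diameter_um=float(d))
        phantom = PlatePhantom(sensor=sensor, colonies=(ColonySeed(cx, cy, disk),), z_um=5.0, seed=seed)
        stack = capture_stack(phantom, schedule, 0.0, supersample=2 * enhancement, noise=NoiseParams(), rng=rng)
        hr = reconstruct_at(stack, sensor, 5.0, enhancement)
        params = SegmentationParams(min_diameter_um=min(20.0, d))
        regions = segment(hr, params)
        if not regions:
            errors[d] = float("nan")
            continue
        best = max(regions, key=lambda r: r.area_um2)
        errors[d] = abs(best.equivalent_diameter_um - d)
    finite = [e for e in errors.values() if np.isfinite(e)]
    return {
        "per_diameter_abs_error_um": {str(k): float(v) for k, v in errors.items()},
        "mean_abs_error_um": float(np.mean(finite)) if len(finite) == len(errors) else float("nan"),
        "hr_pitch_um": sensor.pixel_pitch_um / enhancement,
    }


def focus_recovery_study(
    seed: int,
    n_phantoms: int = 20,
    z_range_um: tuple[float, float] = (15.0, 85.0),
    z_step_um: float = 10.0,
    enhancement: int = 4,
) -> dict:
    """Digital refocusing: recover random sample heights by autofocus.

    Each phantom holds one ~50-μm colony at a random height; the stack is
    captured with a depth-sensitive sweep (coarse_px = 2) and refocused
    over candidates 0…100 μm in 10-μm steps.  Success = |best z − true z|
    within one candidate step.
    """
    sensor = SensorSpec(pixel_pitch_um=2.2, width_px=96, height_px=96)
    schedule = design_scan(sensor, 50.0, enhancement, 8, height_mm=80.0, coarse_px=2)
    candidates = np.arange(0.0, 100.0 + z_step_um / 2, z_step_um)
    rng = np.random.default_rng(seed)
    errors = []
    for k in range(n_phantoms):
        true_z = float(rng.uniform(*z_range_um))
        cx = (sensor.width_px / 2 + rng.uniform(-4, 4)) * sensor.pixel_pitch_um
        cy = (sensor.height_px / 2 + rng.uniform(-4, 4)) * sensor.pixel_pitch_um
        colony = GrowthModel(lag_time_min=0.0, radial_rate_um_per_min=0.1, seed_diameter_um=1.0)
        phantom = PlatePhantom(sensor=sensor, colonies=(ColonySeed(cx, cy, colony),), z_um=true_z, seed=seed + k)
        stack = capture_stack(
            phantom, schedule, 240.0, supersample=2 * enhancement, noise=NoiseParams(), rng=rng
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            profile, _ = autofocus(stack, sensor, candidates, enhancement)
        errors.append(abs(profile.best_z_um - true_z))
    errors = np.asarray(errors)
    return {
        "n": n_phantoms,
        "abs_errors_um": errors.tolist(),
        "success_rate": float(np.mean(errors <= z_step_um)),
        "z_step_um": z_step_um,
    }


def growth_rate_recovery_study(seed: int, n_colonies: int = 35) -> dict:
    """Per-track growth-rate recovery on a multi-colony time-lapse.

    Simulates ``n_colonies`` colonies on a 3 × 3 mm sensor crop, images at
    60-min intervals from 360 to 660 min, segments and links tracks, fits
    each track's diameter-vs-time slope, and compares the fitted radial
    rate v = slope/2 with the colony's true rate.
    """
    sensor = SensorSpec(pixel_pitch_um=2.2, width_px=1364, height_px=1364)
    phantom = PlatePhantom.random(sensor, n_colonies=n_colonies, z_um=5.0, seed=seed, min_separation_um=200.0)
    schedule = ScanSchedule((ONAXIS_80,))
    rng = np.random.default_rng(seed)
    regions_by_time = []
    for t in np.arange(360.0, 661.0, 60.0):
        stack = capture_stack(phantom, schedule, float(t), supersample=2, noise=NoiseParams(), rng=rng)
        hr = reconstruct_at(stack, sensor, phantom.z_um, enhancement=1)
        regions_by_time.append((float(t), segment(hr)))
    tracks = link_tracks(regions_by_time)
    rel_errors = []
    for track in tracks:
        v_fit = fit_growth_rate(track)
        if v_fit is None:
            continue
        x, y = track.last_region.centroid_um
        nearest = min(phantom.colonies, key=lambda c: (c.x_um - x) ** 2 + (c.y_um - y) ** 2)
        v_true = nearest.growth.radial_rate_um_per_min
        rel_errors.append(abs(v_fit - v_true) / v_true)
    rel = np.asarray(rel_errors)
    return {
        "n_tracks": int(rel.size),
        "median_rel_error": float(np.median(rel)) if rel.size else float("nan"),
        "max_rel_error": float(rel.max()) if rel.size else float("nan"),
    }


# ---------------------------------------------------------------------------
# exact-test oracle


def mann_whitney_rank_oracle(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float]:
    """Independent Mann–Whitney oracle via midrank sums.

    U is derived from the rank-sum identity U = R_A − nA(nA+1)/2 with
    midranks for ties; the exact two-sided p enumerates assignments through
    the same rank route.  Kept deliberately separate from the pairwise
    implementation it cross-checks.
    """
    a = list(map(float, group_a))
    b = list(map(float, group_b))
    na, nb = len(a), len(b)
    pooled = np.array(a + b)
    ranks = rankdata(pooled)

    def u_from(indices_a: tuple[int, ...]) -> float:
        return float(ranks[list(indices_a)].sum() - na * (na + 1) / 2.0)

    u_obs = u_from(tuple(range(na)))
    mu = na * nb / 2.0
    dev = abs(u_obs - mu)
    total = extreme = 0
    for combo in itertools.combinations(range(na + nb), na):
        total += 1
        if abs(u_from(combo) - mu) >= dev - 1e-12:
            extreme += 1
    return u_obs, extreme / total


def mann_whitney_agreement_study(seed: int, n_instances: int = 200, max_n: int = 6) -> dict:
    """Exact-test implementation vs the rank-based oracle on random instances.

    Values are drawn from a small integer support so ties are frequent.
    Returns the number of instances where U and p agree exactly.
    """
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_instances):
        na = int(rng.integers(2, max_n + 1))
        nb = int(rng.integers(2, max_n + 1))
        a = rng.integers(0, 6, size=na).astype(float)
        b = rng.integers(0, 6, size=nb).astype(float)
        result = mann_whitney_exact(a, b)
        u_ref, p_ref = mann_whitney_rank_oracle(a, b)
        if abs(result.u_statistic - u_ref) < 1e-9 and abs(result.p_value - p_ref) < 1e-12:
            agree += 1
    return {"n_instances": n_instances, "n_agree": agree}
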