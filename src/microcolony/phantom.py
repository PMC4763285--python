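"""Synthetic phantoms: growing microcolonies rendered as lensless shadow frames.

The generator emulates the study conditions of an on-chip microcolony
assay: roughly disk-shaped absorbing colonies grow on a virtual agar
surface a few micrometres above a 2.2-μm-pitch pixel array and are imaged
from a sweep of oblique illumination angles at 20-minute intervals.

Growth model
------------
Each colony has a normally distributed lag time t0 (default 240 ± 40 min)
after which its radius expands linearly at a per-colony rate v (default
0.10 ± 0.02 μm/min, truncated positive), starting from a single-cell seed
diameter d0 (default 1 μm):

    d(t) = d0 + 2·v·max(0, t − t0)

These defaults put the simulated size statistics in the range of observed
S. epidermidis microcolony growth (~24 μm mean diameter at 360 min rising
to ~93 μm at 700 min).

Optics
------
A colony is an absorbing disk with a smooth sigmoidal edge: transmission
rises from T_center (default 0.35) to 1 over an edge width of ~2 μm, with
the half-depth contour at the nominal radius.  Overlapping colonies
multiply their transmissions, so merged colonies appear as one connected
dark region.  Diffraction of the shadow with height is modelled crudely as
a Gaussian blur with σ proportional to z (0.3 μm per 10 μm of height).
Frames get a low-order polynomial flat-field (±5 % default), Poisson shot
noise at a configurable photon budget, Gaussian read noise, and bit-depth
quantisation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry import (
    IlluminationSource,
    ScanSchedule,
    SensorSpec,
    compute_shadow_shift,
)

# logistic 10-90% width = 2·ln(9)·s  →  s = width / 4.394
_LOGISTIC_1090 = 2.0 * math.log(9.0)


@dataclass(frozen=True)
class GrowthModel:
    """Linear radial growth after a lag: d(t) = d0 + 2·v·max(0, t − t0)."""

    lag_time_min: float
    radial_rate_um_per_min: float
    seed_diameter_um: float = 1.0

    def __post_init__(self) -> None:
        if self.radial_rate_um_per_min < 0:
            raise ValueError("radial growth rate must be >= 0")
        if self.seed_diameter_um <= 0:
            raise ValueError("seed diameter must be > 0")

    def diameter_um(self, t_min: float) -> float:
        return self.seed_diameter_um + 2.0 * self.radial_rate_um_per_min * max(0.0, t_min - self.lag_time_min)


def sample_growth_models(
    n: int,
    rng: np.random.Generator,
    mean_lag_min: float = 240.0,
    sd_lag_min: float = 40.0,
    mean_rate_um_per_min: float = 0.10,
    sd_rate_um_per_min: float = 0.02,
    seed_diameter_um: float = 1.0,
) -> list[GrowthModel]:
    """Draw per-colony growth parameters (rates truncated > 0 by resampling)."""
    lags = rng.normal(mean_lag_min, sd_lag_min, size=n)
    rates = rng.normal(mean_rate_um_per_min, sd_rate_um_per_min, size=n)
    while np.any(rates <= 0):
        bad = rates <= 0
        rates[bad] = rng.normal(mean_rate_um_per_min, sd_rate_um_per_min, size=int(bad.sum()))
    return [
        GrowthModel(lag_time_min=float(max(0.0, t0)), radial_rate_um_per_min=float(v), seed_diameter_um=seed_diameter_um)
        for t0, v in zip(lags, rates)
    ]


@dataclass(frozen=True)
class ColonyOptics:
    """Optical profile of a colony and of the shadow-imaging path."""

    center_transmission: float = 0.35
    edge_width_um: float = 2.0
    blur_um_per_um_z: float = 0.03  # diffraction proxy: 0.3 μm blur per 10 μm height

    def __post_init__(self) -> None:
        if not 0.0 <= self.center_transmission < 1.0:
            raise ValueError("center_transmission must be in [0, 1)")
        if self.edge_width_um <= 0:
            raise ValueError("edge width must be > 0")


@dataclass(frozen=True)
class NoiseParams:
    """Sensor noise and illumination non-uniformity.

    photon_budget
        Mean detected photons per pixel at full (background) illumination;
        ``None`` disables shot noise.
    read_noise_fraction
        Gaussian read noise σ as a fraction of full scale.
    flat_field_amplitude
        Peak deviation of the low-order polynomial flat-field from unity.
    bit_depth
        Output quantisation (8 → 0..255).
    """

    photon_budget: Optional[float] = 10_000.0
    read_noise_fraction: float = 0.005
    flat_field_amplitude: float = 0.05
    bit_depth: int = 8

    @classmethod
    def noiseless(cls, flat_field_amplitude: float = 0.0, bit_depth: int = 8) -> "NoiseParams":
        return cls(photon_budget=None, read_noise_fraction=0.0, flat_field_amplitude=flat_field_amplitude, bit_depth=bit_depth)

    @property
    def full_scale(self) -> int:
        return (1 << self.bit_depth) - 1


@dataclass(frozen=True)
class ColonySeed:
    """One seeded CFU: landing position plus its growth parameters."""

    x_um: float
    y_um: float
    growth: GrowthModel


@dataclass(frozen=True)
class PlatePhantom:
    """Ground-truth synthetic scene: seeded colonies on a virtual sensor."""

    sensor: SensorSpec
    colonies: tuple[ColonySeed, ...]
    z_um: float = 5.0
    seed: int = 0
    optics: ColonyOptics = field(default_factory=ColonyOptics)

    def __post_init__(self) -> None:
        w_um, h_um = self.sensor.fov_um
        for c in self.colonies:
            if not (0.0 <= c.x_um <= w_um and 0.0 <= c.y_um <= h_um):
                raise ValueError(f"colony at ({c.x_um}, {c.y_um}) μm lies outside the {w_um}×{h_um} μm FOV")

    @property
    def density_cfu_per_cm2(self) -> float:
        area_cm2 = self.sensor.fov_mm2 / 100.0
        return len(self.colonies) / area_cm2

    @classmethod
    def random(
        cls,
        sensor: SensorSpec,
        density_cfu_per_cm2: float | None = 80.0,
        n_colonies: int | None = None,
        z_um: float = 5.0,
        seed: int = 0,
        min_separation_um: float = 150.0,
        margin_um: float = 60.0,
        optics: ColonyOptics | None = None,
        **growth_kwargs,
    ) -> "PlatePhantom":
        """Seed colonies uniformly at random with a hard minimum separation.

        The count comes from ``n_colonies`` if given, else from the surface
        density (default 80 CFU/cm², below the <100 CFU/cm² regime used for
        microcolony counting).  The hard-disk separation emulates a
        well-dispersed inoculum; set ``min_separation_um=0`` for pure
        Poisson placement.
        """
        rng = np.random.default_rng(seed)
        w_um, h_um = sensor.fov_um
        if n_colonies is None:
            if density_cfu_per_cm2 is None:
                raise ValueError("give either n_colonies or density_cfu_per_cm2")
            area_cm2 = sensor.fov_mm2 / 100.0
            n_colonies = max(1, int(round(density_cfu_per_cm2 * area_cm2)))
        lo_x, hi_x = margin_um, max(margin_um, w_um - margin_um)
        lo_y, hi_y = margin_um, max(margin_um, h_um - margin_um)
        pts: list[tuple[float, float]] = []
        attempts = 0
        while len(pts) < n_colonies:
            attempts += 1
            if attempts > 200 * n_colonies:
                raise RuntimeError(
                    f"could not place {n_colonies} colonies with min separation {min_separation_um} μm in the FOV"
                )
            x = rng.uniform(lo_x, hi_x)
            y = rng.uniform(lo_y, hi_y)
            if min_separation_um > 0 and any((x - px) ** 2 + (y - py) ** 2 < min_separation_um**2 for px, py in pts):
                continue
            pts.append((x, y))
        growths = sample_growth_models(n_colonies, rng, **growth_kwargs)
        colonies = tuple(ColonySeed(x_um=x, y_um=y, growth=g) for (x, y), g in zip(pts, growths))
        return cls(sensor=sensor, colonies=colonies, z_um=z_um, seed=seed, optics=optics or ColonyOptics())


@dataclass(frozen=True)
class SceneImage:
    """Continuous transmission map on a fine grid (supersampled S× the LR grid)."""

    transmission: np.ndarray  # (height_px·S, width_px·S) float64 in [0, 1]
    pitch_um: float
    supersample: int

    def __post_init__(self) -> None:
        t = self.transmission
        if t.ndim != 2:
            raise ValueError("scene must be a 2-D transmission map")
        if float(t.min()) < -1e-9 or float(t.max()) > 1 + 1e-9:
            raise ValueError("transmission values must lie in [0, 1]")


@dataclass(frozen=True)
class FrameStack:
    """The LR frames of one timepoint: one image per illumination position."""

    frames: np.ndarray  # (n_frames, height_px, width_px) unsigned int
    schedule: ScanSchedule
    t_min: float
    bit_depth: int = 8

    def __post_init__(self) -> None:
        if self.frames.ndim != 3:
            raise ValueError("frames must be (n_frames, height, width)")
        if self.frames.shape[0] != len(self.schedule):
            raise ValueError(
                f"{self.frames.shape[0]} frames but {len(self.schedule)} schedule entries"
            )

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])


def render_scene(phantom: PlatePhantom, t_min: float, supersample: int = 8) -> SceneImage:
    """Render the transmission map of the plate at time ``t`` on a fine grid.

    Colonies whose lag has not elapsed are optically undetectable and are
    not drawn (the scene is exactly T = 1 before the earliest lag time).
    Each visible colony is a radially symmetric absorbing disk with a
    sigmoidal edge whose half-depth contour sits at the nominal radius;
    overlapping colonies multiply their transmissions.
    """
    if t_min < 0:
        raise ValueError("time must be >= 0 min")
    if supersample < 1:
        raise ValueError("supersample factor must be >= 1")
    sensor = phantom.sensor
    s = int(supersample)
    pitch = sensor.pixel_pitch_um / s
    shape = (sensor.height_px * s, sensor.width_px * s)
    t_map = np.ones(shape, dtype=np.float64)
    opt = phantom.optics
    sigma_edge = opt.edge_width_um / _LOGISTIC_1090
    for colony in phantom.colonies:
        if t_min < colony.growth.lag_time_min:
            continue
        radius = colony.growth.diameter_um(t_min) / 2.0
        reach = radius + 6.0 * sigma_edge
        x0, y0 = colony.x_um, colony.y_um
        ix_lo = max(0, int((x0 - reach) / pitch))
        ix_hi = min(shape[1], int((x0 + reach) / pitch) + 2)
        iy_lo = max(0, int((y0 - reach) / pitch))
        iy_hi = min(shape[0], int((y0 + reach) / pitch) + 2)
        if ix_lo >= ix_hi or iy_lo >= iy_hi:
            continue
        xs = (np.arange(ix_lo, ix_hi) + 0.5) * pitch - x0
        ys = (np.arange(iy_lo, iy_hi) + 0.5) * pitch - y0
        r = np.hypot(xs[None, :], ys[:, None])
        # logistic edge: T = Tc at centre, 1 in background, half depth at r = radius
        prof = opt.center_transmission + (1.0 - opt.center_transmission) / (
            1.0 + np.exp((radius - r) / sigma_edge)
        )
        t_map[iy_lo:iy_hi, ix_lo:ix_hi] *= prof
    return SceneImage(transmission=t_map, pitch_um=pitch, supersample=s)


def flat_field_profile(shape: tuple[int, int], amplitude: float) -> np.ndarray:
    """Low-order polynomial illumination profile, peak deviation = amplitude."""
    if amplitude == 0:
        return np.ones(shape, dtype=np.float64)
    h, w = shape
    yn = (np.arange(h) + 0.5) / h - 0.5
    xn = (np.arange(w) + 0.5) / w - 0.5
    basis = 0.8 * xn[None, :] - 0.6 * yn[:, None] + 1.5 * xn[None, :] * yn[:, None] - 0.5 * (
        xn[None, :] ** 2 + yn[:, None] ** 2
    )
    basis = basis / np.abs(basis).max()
    return 1.0 + amplitude * basis


def capture_frame(
    scene: SceneImage,
    source: IlluminationSource,
    z_um: float,
    sensor: SensorSpec,
    noise: NoiseParams | None = None,
    rng: np.random.Generator | None = None,
    blur_sigma_um: float | None = None,
) -> np.ndarray:
    """Record one LR frame of the scene under one illumination position.

    The scene is translated by the physical shadow shift for (source, z),
    blurred by the height-dependent diffraction proxy, box-averaged over
    each LR pixel footprint, multiplied by the flat-field, and passed
    through shot noise, read noise and quantisation.  Content pushed
    outside the FOV is clipped (background fills in).
    """
    noise = noise or NoiseParams()
    exp_h = sensor.height_px * scene.supersample
    exp_w = sensor.width_px * scene.supersample
    if scene.transmission.shape != (exp_h, exp_w):
        raise ValueError(
            f"scene grid {scene.transmission.shape} does not match sensor "
            f"{sensor.height_px}×{sensor.width_px} at supersample {scene.supersample}"
        )
    shift_px = compute_shadow_shift(source, z_um, sensor)
    t_map = scene.transmission
    # physical shift, expressed on the fine grid
    fine_dx = shift_px.dx * sensor.pixel_pitch_um / scene.pitch_um
    fine_dy = shift_px.dy * sensor.pixel_pitch_um / scene.pitch_um
    if fine_dx != 0.0 or fine_dy != 0.0:
        t_map = ndimage.shift(t_map, (fine_dy, fine_dx), order=1, mode="constant", cval=1.0, prefilter=False)
    if blur_sigma_um is None:
        blur_sigma_um = 0.03 * z_um
    if blur_sigma_um > 0:
        t_map = ndimage.gaussian_filter(t_map, blur_sigma_um / scene.pitch_um, mode="nearest")
    s = scene.supersample
    lr = t_map.reshape(sensor.height_px, s, sensor.width_px, s).mean(axis=(1, 3))
    lr = lr * flat_field_profile(lr.shape, noise.flat_field_amplitude)
    if noise.photon_budget is not None:
        if rng is None:
            raise ValueError("shot noise requested but no rng supplied")
        lr = rng.poisson(np.clip(lr, 0.0, None) * noise.photon_budget) / noise.photon_budget
    if noise.read_noise_fraction > 0:
        if rng is None:
            raise ValueError("read noise requested but no rng supplied")
        lr = lr + rng.normal(0.0, noise.read_noise_fraction, size=lr.shape)
    full = noise.full_scale
    counts = np.clip(np.rint(lr * full), 0, full)
    dtype = np.uint8 if noise.bit_depth <= 8 else np.uint16
    return counts.astype(dtype)


def capture_stack(
    phantom: PlatePhantom,
    schedule: ScanSchedule,
    t_min: float,
    supersample: int = 8,
    noise: NoiseParams | None = None,
    rng: np.random.Generator | None = None,
    scene: SceneImage | None = None,
) -> FrameStack:
    """Render (or reuse) the scene at ``t`` and capture every scheduled frame."""
    noise = noise or NoiseParams()
    if scene is None:
        scene = render_scene(phantom, t_min, supersample=supersample)
    frames = np.stack(
        [
            capture_frame(
                scene,
                src,
                phantom.z_um,
                phantom.sensor,
                noise=noise,
                rng=rng,
                blur_sigma_um=phantom.optics.blur_um_per_um_z * phantom.z_um,
            )
            for src in schedule
        ]
    )
    return FrameStack(frames=frames, schedule=schedule, t_min=t_min, bit_depth=noise.bit_depth)


def ground_truth_table(phantom: PlatePhantom, times_min: Sequence[float]) -> pd.DataFrame:
    """Per-timepoint ground truth: positions, diameters and merge components.

    Colonies whose half-depth disks overlap (centre distance < r_i + r_j)
    belong to one merged connected component; merging can only reduce the
    component count below the seeded colony count.  Diameter is reported as
    0 before the lag has elapsed (the colony is optically undetectable).
    """
    rows = []
    n = len(phantom.colonies)
    for t in times_min:
        radii = np.array(
            [c.growth.diameter_um(t) / 2.0 if t >= c.growth.lag_time_min else 0.0 for c in phantom.colonies]
        )
        # union-find over overlapping visible disks
        parent = list(range(n))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            if radii[i] == 0:
                continue
            for j in range(i + 1, n):
                if radii[j] == 0:
                    continue
                ci, cj = phantom.colonies[i], phantom.colonies[j]
                if (ci.x_um - cj.x_um) ** 2 + (ci.y_um - cj.y_um) ** 2 < (radii[i] + radii[j]) ** 2:
                    parent[find(i)] = find(j)
        for cid, colony in enumerate(phantom.colonies):
            rows.append(
                {
                    "timepoint_min": float(t),
                    "colony_id": cid,
                    "x_um": colony.x_um,
                    "y_um": colony.y_um,
                    "true_diameter_um": float(2.0 * radii[cid]),
                    "merged_component_id": find(cid) if radii[cid] > 0 else -1,
                }
            )
    return pd.DataFrame(rows)


def simulate_timelapse(
    phantom: PlatePhantom,
    schedule: ScanSchedule,
    t_start_min: float,
    t_end_min: float,
    interval_min: float = 20.0,
    supersample: int = 8,
    noise: NoiseParams | None = None,
) -> tuple[list[FrameStack], pd.DataFrame]:
    """Simulate the full incubation time-lapse.

    One FrameStack per timepoint at the acquisition interval (default
    20 min), plus the ground-truth colony table.  Deterministic given
    ``phantom.seed``: a single generator seeded from it drives all noise.
    """
    if interval_min <= 0:
        raise ValueError("acquisition interval must be > 0 min")
    if t_end_min < t_start_min:
        raise ValueError("t_end must be >= t_start")
    noise = noise or NoiseParams()
    times = [t_start_min]
    while times[-1] + interval_min <= t_end_min + 1e-9:
        times.append(times[-1] + interval_min)
    rng = np.random.default_rng(phantom.seed)
    stacks = [
        capture_stack(phantom, schedule, t, supersample=supersample, noise=noise, rng=rng) for t in times
    ]
    return stacks, ground_truth_table(phantom, times)
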