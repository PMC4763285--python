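"""Sensor and illumination geometry for lensless shadow imaging.

In a contact-mode (shadow) on-chip microscope the specimen sits a small
height ``z`` above the pixel array and a quasi-point source at height ``H``
(``H`` ≫ ``z``) casts its shadow straight down onto the pixels.  Moving the
source laterally by ``L`` translates the shadow by the similar-triangles
displacement

    Δ = −z / (H − z) · L

measured in the sensor plane.  Because ``z/H`` is tiny (micrometres over
centimetres), a source step of a fraction of a millimetre moves the shadow
by a fraction of a pixel — exactly the sub-pixel sweep that shift-and-add
super-resolution exploits.

Conventions
-----------
Right-handed frame with the origin at the sensor's top-left pixel corner,
``x`` rightward along the width, ``y`` downward along the height, ``z``
upward from the sensor plane.  All lengths are micrometres internally;
source positions and heights are accepted in millimetres at the interface
(fields carry explicit ``_mm`` / ``_um`` suffixes) and converted.  Shift
vectors are expressed in LR-pixel units (physical shift / pixel pitch).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterator, NamedTuple, Sequence

import numpy as np

UM_PER_MM = 1000.0


class GeometryError(ValueError):
    """Raised for physically impossible sensor/source configurations."""


@dataclass(frozen=True)
class SensorSpec:
    """Physical geometry of the monochrome pixel array.

    Defaults describe a 2.2-μm-pitch CMOS sensor with a 5.70 mm × 4.30 mm
    imaging area (~25 mm² field of view).
    """

    pixel_pitch_um: float = 2.2
    width_px: int = 2591
    height_px: int = 1955

    def __post_init__(self) -> None:
        if self.pixel_pitch_um <= 0:
            raise ValueError(f"pixel_pitch_um must be > 0, got {self.pixel_pitch_um}")
        if self.width_px < 1 or self.height_px < 1:
            raise ValueError("sensor must have at least one pixel per axis")

    @property
    def fov_um(self) -> tuple[float, float]:
        """Physical field of view (width, height) in μm."""
        return (self.pixel_pitch_um * self.width_px, self.pixel_pitch_um * self.height_px)

    @property
    def fov_mm2(self) -> float:
        """Field-of-view area in mm²."""
        w, h = self.fov_um
        return (w / UM_PER_MM) * (h / UM_PER_MM)


@dataclass(frozen=True)
class IlluminationSource:
    """A quasi-point light source above the sensor.

    Parameters
    ----------
    offset_mm
        Lateral (Lx, Ly) position in mm relative to the sensor centre.
    height_mm
        Height H of the source above the sensor plane, mm.  Must greatly
        exceed the sample height; validated against z at shift time.
    """

    offset_mm: tuple[float, float]
    height_mm: float

    def __post_init__(self) -> None:
        if self.height_mm <= 0:
            raise GeometryError(f"source height must be > 0 mm, got {self.height_mm}")
        if len(self.offset_mm) != 2:
            raise ValueError("offset_mm must be a 2-vector (Lx, Ly)")


class ShiftVector(NamedTuple):
    """Shadow displacement in LR-pixel units (signed, real-valued)."""

    dx: float
    dy: float


@dataclass(frozen=True)
class ScanSchedule:
    """Ordered illumination positions, one per LR frame of an acquisition."""

    sources: tuple[IlluminationSource, ...]

    def __post_init__(self) -> None:
        if len(self.sources) < 1:
            raise ValueError("a scan schedule needs at least one source position")
        heights = {s.height_mm for s in self.sources}
        if len(heights) > 1:
            raise GeometryError(f"all sources in one schedule must share a height, got {sorted(heights)}")

    def __len__(self) -> int:
        return len(self.sources)

    def __iter__(self) -> Iterator[IlluminationSource]:
        return iter(self.sources)

    @property
    def height_mm(self) -> float:
        return self.sources[0].height_mm

    def to_json_dict(self, sensor: SensorSpec) -> dict:
        """Serialise schedule + sensor geometry as a metadata sidecar dict."""
        return {
            "pixel_pitch_um": sensor.pixel_pitch_um,
            "width_px": sensor.width_px,
            "height_px": sensor.height_px,
            "source_height_mm": self.height_mm,
            "sources": [[s.offset_mm[0], s.offset_mm[1]] for s in self.sources],
        }

    @classmethod
    def from_json_dict(cls, meta: dict) -> tuple["ScanSchedule", SensorSpec]:
        """Rebuild (schedule, sensor) from a sidecar dict; raises on missing keys."""
        for key in ("pixel_pitch_um", "width_px", "height_px", "source_height_mm", "sources"):
            if key not in meta:
                raise KeyError(f"metadata sidecar is missing required field {key!r}")
        sensor = SensorSpec(
            pixel_pitch_um=float(meta["pixel_pitch_um"]),
            width_px=int(meta["width_px"]),
            height_px=int(meta["height_px"]),
        )
        h = float(meta["source_height_mm"])
        sources = tuple(
            IlluminationSource(offset_mm=(float(lx), float(ly)), height_mm=h) for lx, ly in meta["sources"]
        )
        return cls(sources=sources), sensor


def compute_shadow_shift(source: IlluminationSource, z_um: float, sensor: SensorSpec) -> ShiftVector:
    """Shadow displacement of a plane at height ``z`` for one source position.

    Exact similar-triangles form: physical shift = −z/(H−z) · (Lx, Ly),
    converted to LR-pixel units.  A positive lateral source offset pushes
    the shadow the opposite way.

    Raises
    ------
    ValueError
        If ``z`` is negative.
    GeometryError
        If ``z`` reaches or exceeds the source height.
    """
    if z_um < 0:
        raise ValueError(f"sample height z must be >= 0 μm, got {z_um}")
    h_um = source.height_mm * UM_PER_MM
    if z_um >= h_um:
        raise GeometryError(f"sample height z={z_um} μm must be below source height {h_um} μm")
    scale = -z_um / (h_um - z_um)
    lx_um = source.offset_mm[0] * UM_PER_MM
    ly_um = source.offset_mm[1] * UM_PER_MM
    return ShiftVector(
        dx=scale * lx_um / sensor.pixel_pitch_um,
        dy=scale * ly_um / sensor.pixel_pitch_um,
    )


def schedule_shifts(schedule: ScanSchedule, z_um: float, sensor: SensorSpec) -> list[ShiftVector]:
    """Per-frame shadow shifts for a whole schedule (element-wise)."""
    return [compute_shadow_shift(s, z_um, sensor) for s in schedule]


def max_shift_increment(shifts: Sequence[ShiftVector]) -> float:
    """Largest Euclidean step between consecutive shifts, in LR px.

    Used to validate that a schedule sweeps the shadow in sub-pixel
    increments (should stay below 1/E for an enhancement-E reconstruction).
    """
    if len(shifts) < 2:
        return 0.0
    arr = np.asarray(shifts, dtype=float)
    steps = np.diff(arr, axis=0)
    return float(np.hypot(steps[:, 0], steps[:, 1]).max())


def design_scan(
    sensor: SensorSpec,
    z_um: float,
    enhancement: int,
    grid_n: int,
    height_mm: float = 80.0,
    coarse_px: int = 0,
) -> ScanSchedule:
    """Design a source grid giving (coarse + 1/E)-pixel shadow steps at ``z``.

    Inverts the similar-triangles shift relation for the source spacing:

        spacing = pitch · (H − z) · (coarse_px · E + 1) / (z · E)

    and lays out a ``grid_n`` × ``grid_n`` grid centred over the sensor,
    visited in serpentine order so every consecutive pair of frames differs
    by exactly one grid step.  With the default ``coarse_px = 0`` each step
    is a pure sub-pixel shadow increment of 1/E LR pixels.  A nonzero
    ``coarse_px`` adds that many whole pixels to every step: the sub-pixel
    phase coverage (what super-resolution needs) is unchanged, but the
    larger source excursion makes the shadow shifts far more sensitive to
    the assumed sample height, which is what gives digital refocusing its
    depth discrimination.

    Raises
    ------
    GeometryError
        If ``z`` = 0 (an object on the sensor plane casts an unshiftable
        shadow, so no spacing can produce a sub-pixel sweep).
    """
    if enhancement < 1 or grid_n < 1:
        raise ValueError("enhancement and grid_n must both be >= 1")
    if z_um < 0:
        raise ValueError(f"sample height z must be >= 0 μm, got {z_um}")
    h_um = height_mm * UM_PER_MM
    if z_um >= h_um:
        raise GeometryError("sample height must be below the source height")
    if grid_n == 1:
        return ScanSchedule((IlluminationSource(offset_mm=(0.0, 0.0), height_mm=height_mm),))
    if z_um == 0:
        raise GeometryError("cannot design a sweep for z=0: any source spacing gives zero shadow shift")
    if coarse_px < 0:
        raise ValueError("coarse_px must be >= 0")
    spacing_um = (
        sensor.pixel_pitch_um * (h_um - z_um) * (coarse_px * enhancement + 1) / (z_um * enhancement)
    )
    spacing_mm = spacing_um / UM_PER_MM
    centre = (grid_n - 1) / 2.0
    sources = []
    for row in range(grid_n):
        cols = range(grid_n) if row % 2 == 0 else range(grid_n - 1, -1, -1)
        for col in cols:
            sources.append(
                IlluminationSource(
                    offset_mm=((col - centre) * spacing_mm, (row - centre) * spacing_mm),
                    height_mm=height_mm,
                )
            )
    return ScanSchedule(tuple(sources))


def schedule_to_json(schedule: ScanSchedule, sensor: SensorSpec, path) -> None:
    """Write the JSON metadata sidecar for a schedule."""
    with open(path, "w") as fh:
        json.dump(schedule.to_json_dict(sensor), fh, indent=2)


def schedule_from_json(path) -> tuple[ScanSchedule, SensorSpec]:
    """Read a schedule + sensor from a JSON metadata sidecar."""
    with open(path) as fh:
        return ScanSchedule.from_json_dict(json.load(fh))
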