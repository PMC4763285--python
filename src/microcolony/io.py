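"""File formats: TIFF frame stacks, HR images, region tables, sidecars.

Conventions
-----------
* LR frame stacks: one multi-page TIFF per timepoint (one page per
  illumination position), named ``t####min.tif``, with a shared JSON
  metadata sidecar holding the sensor geometry, the scan schedule,
  timestamps, the rng seed and the noise parameters.
* HR images: single-page 32-bit float TIFF plus a JSON sidecar with the
  focal depth, enhancement factor and grid pitch.
* Region tables and ground truth: plain CSV via pandas; unknown columns
  and sidecar fields survive a round-trip untouched.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .geometry import ScanSchedule, SensorSpec
from .phantom import FrameStack, NoiseParams
from .reconstruct import HRImage
from .segment import ColonyRegion

REGION_COLUMNS = [
    "timepoint_min",
    "label",
    "x_um",
    "y_um",
    "area_um2",
    "equivalent_diameter_um",
    "bbox_x_um",
    "bbox_y_um",
    "bbox_w_um",
    "bbox_h_um",
    "touches_border",
    "counted",
]


def stack_filename(t_min: float) -> str:
    return f"t{int(round(t_min)):04d}min.tif"


def write_timelapse_meta(
    path,
    schedule: ScanSchedule,
    sensor: SensorSpec,
    timestamps_min: Sequence[float],
    rng_seed: int | None = None,
    noise: NoiseParams | None = None,
    extra: dict | None = None,
) -> None:
    """Write the shared JSON sidecar for a set of frame-stack TIFFs."""
    meta = schedule.to_json_dict(sensor)
    meta["timestamps_min"] = [float(t) for t in timestamps_min]
    if rng_seed is not None:
        meta["rng_seed"] = int(rng_seed)
    if noise is not None:
        meta["noise_params"] = dataclasses.asdict(noise)
    if extra:
        meta.update(extra)
    Path(path).write_text(json.dumps(meta, indent=2))


def read_timelapse_meta(path) -> dict:
    meta = json.loads(Path(path).read_text())
    for key in ("pixel_pitch_um", "width_px", "height_px", "source_height_mm", "sources"):
        if key not in meta:
            raise KeyError(f"metadata sidecar {path} is missing required field {key!r}")
    return meta


def write_frame_stack(path, stack: FrameStack) -> None:
    """Write one timepoint's frames as a multi-page TIFF."""
    tifffile.imwrite(path, stack.frames, photometric="minisblack", metadata={"t_min": stack.t_min})


def read_frame_stack(path, sidecar) -> tuple[FrameStack, SensorSpec]:
    """Read a multi-page TIFF + sidecar back into a FrameStack.

    The timepoint is recovered from the ``t####min.tif`` filename.
    """
    meta = sidecar if isinstance(sidecar, dict) else read_timelapse_meta(sidecar)
    schedule, sensor = ScanSchedule.from_json_dict(meta)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    name = Path(path).stem
    t_min = 0.0
    if name.startswith("t") and name.endswith("min"):
        try:
            t_min = float(name[1:-3])
        except ValueError:
            pass
    bit_depth = int(meta.get("noise_params", {}).get("bit_depth", 8 * frames.dtype.itemsize))
    stack = FrameStack(frames=frames, schedule=schedule, t_min=t_min, bit_depth=bit_depth)
    return stack, sensor


def write_hr(path, image: HRImage, sidecar=None) -> None:
    """Write an HR image as 32-bit float TIFF with a JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(
        path,
        image.data.astype(np.float32),
        photometric="minisblack",
        metadata={
            "focal_z_um": image.focal_z_um,
            "enhancement": image.enhancement,
            "hr_pitch_um": image.hr_pitch_um,
            "t_min": image.t_min,
        },
    )
    sidecar = Path(sidecar) if sidecar is not None else path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "focal_z_um": image.focal_z_um,
                "enhancement": image.enhancement,
                "hr_pitch_um": image.hr_pitch_um,
                "t_min": image.t_min,
            },
            indent=2,
        )
    )


def read_hr(path, sidecar=None) -> HRImage:
    path = Path(path)
    sidecar = Path(sidecar) if sidecar is not None else path.with_suffix(".json")
    meta = json.loads(sidecar.read_text())
    for key in ("focal_z_um", "enhancement", "hr_pitch_um"):
        if key not in meta:
            raise KeyError(f"HR sidecar {sidecar} is missing required field {key!r}")
    data = tifffile.imread(path).astype(np.float64)
    return HRImage(
        data=data,
        enhancement=int(meta["enhancement"]),
        hr_pitch_um=float(meta["hr_pitch_um"]),
        focal_z_um=float(meta["focal_z_um"]),
        t_min=float(meta.get("t_min", 0.0)),
    )


def regions_to_dataframe(regions: Sequence[ColonyRegion]) -> pd.DataFrame:
    rows = []
    for r in regions:
        rows.append(
            {
                "timepoint_min": r.t_min,
                "label": r.label,
                "x_um": r.centroid_um[0],
                "y_um": r.centroid_um[1],
                "area_um2": r.area_um2,
                "equivalent_diameter_um": r.equivalent_diameter_um,
                "bbox_x_um": r.bbox_um[0],
                "bbox_y_um": r.bbox_um[1],
                "bbox_w_um": r.bbox_um[2],
                "bbox_h_um": r.bbox_um[3],
                "touches_border": r.touches_border,
                "counted": r.counted,
            }
        )
    return pd.DataFrame(rows, columns=REGION_COLUMNS)


def regions_from_dataframe(df: pd.DataFrame) -> list[ColonyRegion]:
    required = {"timepoint_min", "label", "x_um", "y_um", "area_um2", "equivalent_diameter_um", "counted"}
    missing = required - set(df.columns)
    if missing:
        raise KeyError(f"regions table is missing required columns: {sorted(missing)}")
    regions = []
    for _, row in df.iterrows():
        regions.append(
            ColonyRegion(
                label=int(row["label"]),
                area_um2=float(row["area_um2"]),
                equivalent_diameter_um=float(row["equivalent_diameter_um"]),
                centroid_um=(float(row["x_um"]), float(row["y_um"])),
                bbox_um=(
                    float(row.get("bbox_x_um", 0.0)),
                    float(row.get("bbox_y_um", 0.0)),
                    float(row.get("bbox_w_um", 0.0)),
                    float(row.get("bbox_h_um", 0.0)),
                ),
                touches_border=bool(row.get("touches_border", False)),
                counted=bool(row["counted"]),
                t_min=float(row["timepoint_min"]),
            )
        )
    return regions


def write_regions_csv(path, regions) -> None:
    """Write regions (list of ColonyRegion, or a DataFrame) to CSV.

    A DataFrame is written as-is, so extra columns round-trip unchanged.
    """
    df = regions if isinstance(regions, pd.DataFrame) else regions_to_dataframe(regions)
    df.to_csv(path, index=False)


def read_regions_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"timepoint_min", "label", "equivalent_diameter_um"} - set(df.columns)
    if missing:
        raise KeyError(f"regions CSV {path} is missing required columns: {sorted(missing)}")
    return df


def regions_by_time_from_dataframe(df: pd.DataFrame) -> list[tuple[float, list[ColonyRegion]]]:
    """Group a regions table into the per-timepoint structure tracking expects."""
    out = []
    for t, sub in df.groupby("timepoint_min"):
        out.append((float(t), regions_from_dataframe(sub)))
    out.sort(key=lambda p: p[0])
    return out
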