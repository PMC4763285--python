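# microcolony

Lensless on-chip microscopy simulation and real-time bacterial
microcolony counting.

## The problem

Counting colony-forming units (CFU) is the workhorse assay of quantitative
microbiology, but conventional plate counting waits ~24 h for colonies to
become visible to the naked eye (~1 mm). A chip-scale alternative grows the
culture **directly on a CMOS pixel array** (pixel pitch 2.2 μm, imaging area
5.7 mm × 4.3 mm ≈ 25 mm²): each microcolony casts a shadow on the pixels
beneath it, so the whole field of view is imaged continuously without lenses
or stages, and colonies only ~20 μm across — reachable within ~6 h of
incubation — can be detected, sized and enumerated.

Raw shadow images are limited to roughly twice the pixel pitch (Nyquist).
**Sub-pixel sweeping microscopy (SPSM)** breaks that limit: a light source at
height *H* above the sensor is stepped laterally, and by similar triangles a
sample plane at height *z* casts a shadow displaced by

    Δ = −z/(H − z) · (Lx, Ly)

for source offset (Lx, Ly). Micrometre-scale *z* over centimetre-scale *H*
turns sub-millimetre source steps into **sub-pixel shadow shifts**. Capturing
one low-resolution (LR) frame per source position and depositing each
de-shifted LR pixel onto an *E*×-finer grid (shift-and-add, hit-count
normalised) reconstructs a high-resolution (HR) image at pitch/E. Because
the shifts depend on the assumed *z*, reconstructing at a sweep of candidate
depths and scoring each with a Tenengrad sharpness metric gives **digital
refocusing** with no moving parts.

Downstream, the classic three-step counting algorithm runs per timepoint:
load the HR image, segment colony regions by edge detection (Sobel gradient
→ Otsu threshold → closing → hole filling), and enumerate/size them. Region
area *A* is reported as the **equivalent diameter** d = 2·√(A/π), with
d ≥ 20 μm the reliable-enumeration cutoff. Regions are linked through time
by nearest-centroid tracking (with merge bookkeeping), yielding size
distributions vs incubation time, count-vs-time curves with 95 %-of-maximum
saturation detection, surface densities, titer estimates
(count · dilution / volume), and an exact small-sample Mann–Whitney U test
for comparing assays.

Because no public raw data exist for this kind of instrument, the package
includes a first-class **phantom simulator**: colonies with normally
distributed lag times and linear radial growth rates are rendered as
absorbing disks with smooth edges and imaged through the full forward model
(shadow shift, height-dependent diffraction blur, pixel-aperture
integration, polynomial flat-field, shot/read noise, quantisation). Every
claim the pipeline makes is validated against this simulator's ground truth.

## Worked example

Simulate a 1 mm × 1 mm sensor crop with five colonies, reconstruct at E=2,
segment, track, and report:

```python
import numpy as np
from microcolony import (
    SensorSpec, PlatePhantom, design_scan, simulate_timelapse,
    reconstruct_at, segment, build_report, fit_growth_rate,
)

sensor = SensorSpec(pixel_pitch_um=2.2, width_px=454, height_px=454)
phantom = PlatePhantom.random(sensor, n_colonies=5, z_um=5.0, seed=5,
                              min_separation_um=150.0)
schedule = design_scan(sensor, z_um=5.0, enhancement=2, grid_n=4)
stacks, truth = simulate_timelapse(phantom, schedule, t_start_min=360.0,
                                   t_end_min=480.0, interval_min=40.0,
                                   supersample=4)

regions_by_time = []
for stack in stacks:
    hr = reconstruct_at(stack, sensor, z_um=5.0, enhancement=2)
    regions_by_time.append((stack.t_min, segment(hr)))

report, tracks = build_report(regions_by_time, fov_mm2=sensor.fov_mm2,
                              sample_volume_ul=0.04)
```

Output:

```
counts per timepoint: (3, 4, 5, 5)
mean diameter (um):   [26.9, 30.5, 34.7, 41.4]
saturation time:      440.0 min
density:              501.2 CFU/cm2
titer:                1.25e+05 CFU/mL
fitted radial rates:  [0.087, 0.098, 0.076, 0.066, 0.09] um/min
true radial rates:    [0.065, 0.098, 0.077, 0.087, 0.09]
```

Reading: at 360 min three of the five colonies have passed the 20-μm
counting threshold; by 440 min (the 95 %-saturation time) all five are
counted. The mean counted diameter grows from 27 to 41 μm across the two
hours. The titer converts the final count through the stated 0.04 μL
inoculum; per-track linear fits of diameter vs time recover each colony's
radial growth rate (order of the lists may differ — match tracks to seeds
by position).

The same pipeline runs from the shell:

```
microcolony run --config config.yaml --seed 5
microcolony simulate --out run/ --seed 5
microcolony reconstruct --stack run/t0360min.tif --meta run/meta.json --z 5 --enhance 4 --out run/hr.tif
microcolony segment --hr run/hr.tif --out run/regions.csv
microcolony report --regions run/regions.csv --volume-ul 1 --out run/report.json
```

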