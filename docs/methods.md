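# Methods

This note records the models, parameter choices and numerical decisions
behind the package, and what its validation studies do and do not
demonstrate.

## Imaging model

**Geometry.** Right-handed frame, origin at the sensor's top-left pixel
corner; x rightward, y downward, z upward from the sensor plane. All
internal lengths are μm; source positions and heights enter in mm and are
converted at the interface. The shadow of a plane at height z under a
source at lateral offset L = (Lx, Ly) and height H is displaced by the
exact similar-triangles form Δ = −z/(H − z)·L (we do not use the small-z
approximation −z·L/H; the exact form costs nothing and removes an
ambiguity). Shift vectors are expressed in LR-pixel units (physical
displacement / pixel pitch, 2.2 μm by default).

One global shift per frame is used: the field-position dependence of the
shift across the FOV (the shadow of an off-centre point shifts by an extra
+z/(H − z)·x₀) is neglected, as shift-and-add onto a single larger matrix
implies. At the default geometry (H = 80 mm, z ≤ 100 μm) the neglected term
is below 1.25 × 10⁻⁶ LR px per μm of field position — orders of magnitude
under the deposit rounding of 1/(2E) px. The ray-tracing oracle in the test
suite quantifies the agreement of the central-ray model to 1e-9.

**Scan design.** `design_scan` inverts the shift relation for the source
spacing that yields consecutive shadow steps of 1/E LR px at the design
height: spacing = pitch·(H − z)·(coarse_px·E + 1)/(z·E). The grid is visited
in serpentine order so *every* consecutive frame pair differs by exactly one
step; a raster order would break the constant-increment property at row
wraps. H and the grid shape are free parameters (the bench geometry is not
standardised); defaults are H = 80 mm and an 8×8 grid, giving ≥ E² coverage
of the sub-pixel phase lattice at E = 4.

The `coarse_px` option (default 0) adds whole-pixel steps to the sweep.
Sub-pixel phase coverage — what super-resolution needs — is unchanged, but
the larger source excursion makes the shifts proportionally more sensitive
to the assumed height. This matters for refocusing: with a pure 1/E sweep
the whole schedule spans < 2 LR px of shift, so a wrong z perturbs the
deposit positions by far less than the LR pixel aperture and *no* sharpness
metric can rank depths. The depth-recovery study therefore acquires with
coarse_px = 2 (steps of 2¼ px, source excursion ±28 mm), which is the
regime in which a real instrument's LED array operates.

## Phantom simulator

The generator emulates the study conditions of an on-chip microcolony
assay. What it models, with defaults and rationale:

- **Growth law**: diameter d(t) = d0 + 2·v·max(0, t − t0); per-colony lag
  t0 ~ Normal(240, 40) min, radial rate v ~ Normal(0.10, 0.02) μm/min
  truncated positive, seed diameter d0 = 1 μm (a single coccus). Observed
  microcolony growth is reported only as monotonic; the linear-radial form
  is the simplest law whose size statistics land in the observed range
  (~24 μm mean at 360 min rising to ~93 μm at 700 min), and the model is
  pluggable.
- **Colony optics**: absorbing disk, centre transmission 0.35, logistic
  edge with 10–90 % width 2 μm whose half-depth contour sits exactly at the
  nominal radius (so "diameter" is unambiguous); overlapping colonies
  multiply transmissions, so merged colonies form one connected dark
  region. Colonies are drawn only once their lag has elapsed — a pre-lag
  single cell is treated as optically undetectable.
- **Height and diffraction**: colonies sit at z = 5 μm by default (a thin
  liquid layer above the pixels); shadow diffraction is proxied by a
  Gaussian blur with σ = 0.3 μm per 10 μm of height. Exact Fresnel
  propagation is out of scope; the proxy reproduces the qualitative
  resolution loss with height.
- **Sensor chain**: the scene (supersampled S× the LR grid, S ≥ 2E) is
  translated by the physical shadow shift, blurred, box-averaged over each
  pixel aperture, multiplied by a low-order polynomial flat-field (±5 %
  peak), then Poisson shot noise at a 10 000-photon background budget,
  Gaussian read noise (0.5 % full scale), and 8-bit quantisation.
- **Seeding**: uniform placement with a hard minimum separation (default
  150 μm), emulating a well-dispersed inoculum whose colonies do not merge
  over the simulated window; `min_separation_um=0` recovers Poisson
  placement, under which close pairs merge and the merged-component ground
  truth tracks them. Surface density is the generator's primitive (default
  80 CFU/cm²); the relationship between an inoculum drop volume, its spread
  area, and the counted FOV is deliberately left to explicit titer
  parameters.

Everything is deterministic given the phantom seed; time-lapses are
reproducible byte-for-byte.

**What the phantom does not emulate** — and hence what passing tests do not
show about real data: non-circular colony morphology (lobed edges, 3-D
thickness, internal texture), motility and nutrient-depletion growth
slowdown, agar autofluorescence or debris, sensor fixed-pattern noise and
defective pixels, illumination-source extent (partial coherence), and true
diffraction. Recovery rates measured here are upper bounds on field
performance.

## Reconstruction

Shift-and-add with nearest-bin deposit: LR pixel i of a frame with shift s
lands in HR bin round((i+0.5)·E − 0.5 − s·E); a parallel hit-count grid
normalises collisions, and never-hit bins are filled by iterated averaging
of filled neighbours (equivalent to bilinear interpolation from the filled
frontier). All accumulation is double precision; outputs are stored as
32-bit float TIFF with a JSON sidecar (focal z, E, grid pitch). With E = 1
and zero shifts the operation reduces exactly to the arithmetic frame mean,
which the tests pin. A deconvolution post-step for the pixel-aperture box
blur is deliberately absent: the HR image keeps the 2.2-μm aperture blur,
sampled at pitch/E, which is sufficient to resolve a two-LR-pixel point
pair and is what the enumeration stages consume.

**Focus metric.** Tenengrad (mean squared 3×3 Sobel magnitude) after a
Gaussian prefilter of σ = 2 HR px. The prefilter is essential, not
cosmetic: a *mis*aligned reconstruction is grainy at the single-bin scale
and that grain carries more raw gradient energy than the correctly aligned
image, so unfiltered Tenengrad ranks defocused reconstructions *higher*.
Filtering at the feature scale (the colony edge spans ~4–5 HR px after the
aperture blur) restores the expected unimodal score-vs-depth profile;
variance-of-Laplacian is provided as an alternative with the same
prefilter. Ties break toward the smaller candidate z, and an endpoint
maximum raises a warning.

## Segmentation and sizing

Pipeline: flat-field correction (divide by a copy smoothed at 250 μm ≫ any
colony) → Sobel gradient magnitude → threshold → closing (disk, 2 μm) →
hole filling → removal of regions < 20 μm² → 8-connected labelling. The
threshold is Otsu on the gradient image, floored at median + 8·1.4826·MAD
of the gradient: on a blank noisy frame Otsu falls inside the noise
distribution and would mark half the pixels, while the robust floor keeps
only genuine edges (on frames with real colonies the Otsu value sits far
above the floor and wins). All geometric parameters are physical (μm), so
behaviour is invariant to E. Regions touching the FOV border are counted
but flagged by default (`border_policy="flag"`); excluding them would bias
counts on a 25 mm² FOV.

**Sizing refinement.** The gradient band spans the full width of the
colony's smooth edge, so the filled mask systematically overshoots the
half-depth boundary — measured at ≈ +2.9 μm on disk phantoms, beyond the
2-HR-px accuracy the assay needs. `refine_sizing` (default on) re-measures
each *detected* region's area at the half-depth intensity contour: within a
padded bounding box, pixels darker than the midpoint between the local
background (median outside the mask) and the colony core (5th percentile
inside) are counted, restricted to the connected component overlapping the
detection. Because the phantom's half-depth contour sits at the nominal
radius, this estimator is unbiased (measured error ≈ 0.05 μm); detection
and counting still come solely from the edge pipeline. Merged colonies are
deliberately kept as one region (no watershed splitting), matching how a
simple edge-detection counter under-counts after contact.

## Tracking and statistics

Greedy nearest-centroid linking between consecutive timepoints, closest
pairs first, each region continuing at most one track, matches beyond
15 μm rejected (colony centroids barely move between 20-min frames).
Unmatched regions start tracks. Merge bookkeeping extends the greedy rule:
a merged blob's centroid can lie farther than the link distance from every
parent (two touching 40-μm colonies leave each parent 20 μm away), so an
unmatched track also claims a region when its centroid falls within the
region's equivalent radius plus the link slack. Of all tracks claiming one
region the largest-area one survives; the others record `merged_into` and
the merge time. This conserves identity: births = active tracks +
cumulative merges.

Derived statistics: per-timepoint mean and sample SD (n−1; n = 1 reported
as SD 0 and flagged) of counted diameters; saturation time = earliest
timepoint whose count reaches 95 % (configurable) of the final count;
density = final count / FOV area; titer = count · dilution / volume. The
Mann–Whitney U test uses the pairwise definition U = Σ 1[a > b] + ½·1[a=b]
and an exact two-sided p by full enumeration of all C(nA+nB, nA)
assignments of the pooled values (deviation criterion |U′ − nA·nB/2| ≥
|U − nA·nB/2|); with group sizes ≈ 5 the exact test is both feasible and
the statistically correct choice, and ties are handled exactly. The
countable-density bound scales inversely with colony footprint area:
base_density·(base_d/target_d)², connecting the classic <10 CFU/cm²
guideline at 1 mm to 25 000 CFU/cm² at 20 μm.

## Validation studies and problem sizes

The studies in `microcolony.validation` (asserted by the test suite, and
reported numerically by `scripts/acceptance.py`) use these sizes, chosen so
each completes in seconds to a couple of minutes on one CPU:

- **Two-point resolution**: 48×48-px sensor crop, opaque 1.6-μm dots
  4.4 μm apart straddling a pixel boundary (the blind sampling phase),
  E = 4 with the designed 8×8 sweep, default noise. Resolved means a ≥20 %
  intensity dip between the points; the LR comparison is the single
  on-axis frame.
- **Count recovery**: 50 colonies, ≥150 μm apart, on the full
  5.7 × 4.3 mm sensor grown to 600 min (mean diameter ~73 μm), scene
  supersample 2, one noiseless and five noisy captures, E = 1
  reconstruction. Enumeration of grown colonies needs no super-resolution —
  a ≥20-μm colony is already ~10 LR px across — so the study exercises the
  counting rule, not the sweep.
- **Sizing**: single disks of 20/40/80 μm, off-grid centres, E = 4
  reconstruction at the true height, default noise.
- **Focus recovery**: 20 phantoms, one ~50-μm colony each, true z uniform
  in 15–85 μm, coarse_px = 2 acquisition designed at z = 50 μm, candidates
  0–100 μm step 10.
- **Growth-rate recovery**: 35 colonies on a 3 × 3 mm crop, frames every
  60 min from 360 to 660 min, E = 1, tracks fitted by least squares
  (v = slope/2) and matched to seeds by position.
- **Exact-test oracle**: 200 random instances, group sizes 2–6, integer
  support 0–5 so ties are frequent, compared against an independent
  rank-sum-identity enumeration.
- **Degenerate oracles**: E = 1/zero-shift reconstruction vs the frame
  mean (exact equality), and the shift model vs parametric ray–plane
  intersection over 100 random geometries (≤ 1e-9 relative).

## Known limitations

- The shift model is central-ray and global per frame; very tall samples
  or very low sources would need the field-dependent term.
- Shift-and-add trusts the geometric shifts; there is no blind
  registration, so a mis-specified H or source grid degrades silently
  (autofocus recovers z only).
- The segmentation is intensity/edge-based with no shape prior; touching
  colonies are counted as one, and heavy debris would be counted as
  colonies.
- The exact Mann–Whitney enumeration is limited to group sizes ≤ 10
  (C(20,10) = 184 756 assignments); larger samples belong to asymptotic
  implementations elsewhere.
- Titer estimation treats volume and dilution as exact inputs; inoculum
  spread beyond the FOV is the caller's responsibility.
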