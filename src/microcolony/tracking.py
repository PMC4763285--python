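"""Colony tracking through time and enumeration statistics.

Links segmented regions across timepoints by greedy nearest-centroid
matching (colony centroids barely move between 20-min frames), records
merge events, and derives the headline outputs of a real-time microcolony
assay: size distribution versus incubation time, count-versus-time with
95 %-of-maximum saturation detection, titer estimates, the density-scaling
bound for countable colony size, and an exact Mann–Whitney U comparison of
two assays' titers.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .segment import ColonyRegion


@dataclass
class ColonyTrack:
    """One colony's identity through time.

    ``regions`` maps timepoint (min) → ColonyRegion.  If the colony merged
    into a neighbour, ``merged_into`` holds the surviving track id and
    ``merge_time_min`` the timepoint at which the regions became one.
    """

    track_id: int
    regions: dict[float, ColonyRegion] = field(default_factory=dict)
    merged_into: Optional[int] = None
    merge_time_min: Optional[float] = None

    @property
    def birth_time_min(self) -> float:
        return min(self.regions)

    @property
    def last_time_min(self) -> float:
        return max(self.regions)

    @property
    def last_region(self) -> ColonyRegion:
        return self.regions[self.last_time_min]

    def diameters(self) -> tuple[np.ndarray, np.ndarray]:
        """(times, equivalent diameters) sorted by time."""
        ts = np.array(sorted(self.regions))
        ds = np.array([self.regions[t].equivalent_diameter_um for t in ts])
        return ts, ds


def link_tracks(
    regions_by_time: Sequence[tuple[float, Sequence[ColonyRegion]]],
    max_link_distance_um: float = 15.0,
) -> list[ColonyTrack]:
    """Greedy nearest-centroid linking of regions into tracks.

    Between consecutive timepoints, (track, region) pairs are matched
    closest-first; each region continues at most one track and matches
    beyond ``max_link_distance_um`` are rejected.  Unmatched regions start
    new tracks.  Tracks left unmatched whose centroid falls inside an
    already-matched region (within its equivalent radius) are merge
    parents: of all tracks claiming one region, the largest-area one
    survives and the others record ``merged_into`` it.  (The merged blob's
    centroid can sit farther than the link distance from either parent, so
    merge detection uses the region's own extent.)
    """
    items = sorted(regions_by_time, key=lambda p: p[0])
    tracks: list[ColonyTrack] = []
    active: list[ColonyTrack] = []
    next_id = 0
    for t, regions in items:
        labels = [r.label for r in regions]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate region labels at t={t} min")
        regions = list(regions)
        claimed: dict[int, list[ColonyTrack]] = {}  # region index -> claiming tracks
        matched_tracks: set[int] = set()
        matched_regions: set[int] = set()
        pairs = []
        for ti, track in enumerate(active):
            tx, ty = track.last_region.centroid_um
            for ri, region in enumerate(regions):
                rx, ry = region.centroid_um
                d = math.hypot(rx - tx, ry - ty)
                pairs.append((d, ti, ri))
        pairs.sort(key=lambda p: (p[0], p[1], p[2]))
        # pass 1: continuation matches, closest first
        for d, ti, ri in pairs:
            if d > max_link_distance_um:
                break
            if ti in matched_tracks or ri in matched_regions:
                continue
            matched_tracks.add(ti)
            matched_regions.add(ri)
            claimed.setdefault(ri, []).append(active[ti])
        # pass 2: merge detection for still-unmatched tracks.  A merged
        # blob's centroid may sit far from every parent centroid, so an
        # unmatched track claims a region when its centroid lies within the
        # region's own equivalent radius (+ the link slack).
        for d, ti, ri in pairs:
            if ti in matched_tracks:
                continue
            region = regions[ri]
            if d <= region.equivalent_diameter_um / 2.0 + max_link_distance_um:
                matched_tracks.add(ti)
                matched_regions.add(ri)
                claimed.setdefault(ri, []).append(active[ti])
        new_active: list[ColonyTrack] = []
        for ri, region in enumerate(regions):
            claimants = claimed.get(ri, [])
            if not claimants:
                track = ColonyTrack(track_id=next_id, regions={t: region})
                next_id += 1
                tracks.append(track)
                new_active.append(track)
                continue
            survivor = max(claimants, key=lambda tr: (tr.last_region.area_um2, -tr.track_id))
            survivor.regions[t] = region
            new_active.append(survivor)
            for other in claimants:
                if other is not survivor:
                    other.merged_into = survivor.track_id
                    other.merge_time_min = t
        active = new_active
    return tracks


@dataclass(frozen=True)
class SizeDistribution:
    mean_diameter_um: float
    sd_diameter_um: float
    n: int
    degenerate: bool  # n < 2: SD reported as 0 and flagged


def size_distribution(tracks: Sequence[ColonyTrack], t_min: float) -> SizeDistribution:
    """Mean and sample SD (n−1) of counted regions' diameters at time ``t``."""
    diams = [
        tr.regions[t_min].equivalent_diameter_um
        for tr in tracks
        if t_min in tr.regions and tr.regions[t_min].counted and tr.merged_into is None
    ]
    n = len(diams)
    if n == 0:
        warnings.warn(f"no counted colonies at t={t_min} min; size distribution undefined", stacklevel=2)
        return SizeDistribution(mean_diameter_um=float("nan"), sd_diameter_um=float("nan"), n=0, degenerate=True)
    mean = float(np.mean(diams))
    sd = float(np.std(diams, ddof=1)) if n > 1 else 0.0
    return SizeDistribution(mean_diameter_um=mean, sd_diameter_um=sd, n=n, degenerate=n < 2)


def saturation_time(
    times_min: Sequence[float],
    counts: Sequence[int],
    fraction: float = 0.95,
) -> Optional[float]:
    """Earliest timepoint whose count reaches ``fraction`` of the final count.

    Mirrors the 95 %-of-maximum readout rule for count saturation.  Returns
    None (with a warning) if every count is zero.
    """
    times = list(times_min)
    counts = list(counts)
    if len(times) != len(counts) or not times:
        raise ValueError("times and counts must be equal-length, non-empty sequences")
    final = counts[-1]
    if max(counts) == 0:
        warnings.warn("all counts are zero; saturation time undefined", stacklevel=2)
        return None
    target = fraction * final
    for t, c in zip(times, counts):
        if c >= target:
            return float(t)
    return float(times[-1])  # pragma: no cover - final count always satisfies itself


def estimate_titer(final_count: float, sample_volume_ul: float, dilution_factor: float = 1.0) -> float:
    """Concentration in CFU/mL from a count, inoculum volume and dilution."""
    if sample_volume_ul <= 0:
        raise ValueError("sample volume must be > 0 μL")
    if dilution_factor < 1:
        raise ValueError("dilution factor must be >= 1")
    if final_count < 0:
        raise ValueError("count must be >= 0")
    return final_count * dilution_factor / (sample_volume_ul * 1e-3)


def density_scale_bound(
    base_density_cfu_per_cm2: float,
    base_diameter_um: float,
    target_diameter_um: float,
) -> float:
    """Scale a recommended countable density to a different colony size.

    The non-merging colony density scales inversely with colony footprint
    area, i.e. with the square of the diameter ratio: the classic
    <10 CFU/cm² guideline for 1-mm naked-eye colonies becomes
    <25,000 CFU/cm² for 20-μm microcolonies.
    """
    if base_density_cfu_per_cm2 <= 0:
        raise ValueError("base density must be > 0")
    if base_diameter_um <= 0 or target_diameter_um <= 0:
        raise ValueError("diameters must be > 0")
    return base_density_cfu_per_cm2 * (base_diameter_um / target_diameter_um) ** 2


@dataclass(frozen=True)
class AssayComparison:
    """Exact two-sided Mann–Whitney comparison of two titer groups."""

    group_a: tuple[float, ...]
    group_b: tuple[float, ...]
    u_statistic: float
    p_value: float


def mann_whitney_exact(group_a: Sequence[float], group_b: Sequence[float]) -> AssayComparison:
    """Exact two-sided Mann–Whitney U test by full permutation enumeration.

    U counts pairs where a > b, plus half the tied pairs.  The two-sided p
    is the fraction of all C(nA+nB, nA) assignments of the pooled values
    whose |U′ − nA·nB/2| is at least the observed deviation — exact even
    with ties, and appropriate for the tiny group sizes (n ≈ 5) typical of
    assay comparisons.
    """
    a = [float(x) for x in group_a]
    b = [float(x) for x in group_b]
    if not a or not b:
        raise ValueError("both groups must be non-empty")
    na, nb = len(a), len(b)
    if na > 10 or nb > 10:
        raise ValueError("exact enumeration supports group sizes up to 10")

    def u_stat(xs: Sequence[float], ys: Sequence[float]) -> float:
        u = 0.0
        for x in xs:
            for y in ys:
                if x > y:
                    u += 1.0
                elif x == y:
                    u += 0.5
        return u

    u_obs = u_stat(a, b)
    mu = na * nb / 2.0
    obs_dev = abs(u_obs - mu)
    pooled = a + b
    idx = range(na + nb)
    total = 0
    extreme = 0
    for combo in itertools.combinations(idx, na):
        in_a = set(combo)
        xs = [pooled[i] for i in in_a]
        ys = [pooled[i] for i in idx if i not in in_a]
        total += 1
        if abs(u_stat(xs, ys) - mu) >= obs_dev - 1e-12:
            extreme += 1
    return AssayComparison(
        group_a=tuple(a), group_b=tuple(b), u_statistic=u_obs, p_value=extreme / total
    )


def fit_growth_rate(track: ColonyTrack, min_points: int = 3) -> Optional[float]:
    """Radial growth rate v (μm/min) from a linear fit of diameter vs time.

    The diameter grows at 2·v, so v = slope/2.  Returns None for tracks
    with fewer than ``min_points`` observations.
    """
    ts, ds = track.diameters()
    if ts.size < min_points:
        return None
    slope = np.polyfit(ts, ds, 1)[0]
    return float(slope / 2.0)


@dataclass(frozen=True)
class TimeSeriesReport:
    """Per-timepoint enumeration summary plus assay-level scalars."""

    times_min: tuple[float, ...]
    counts: tuple[int, ...]
    mean_diameters_um: tuple[float, ...]
    sd_diameters_um: tuple[float, ...]
    saturation_time_min: Optional[float]
    final_count: int
    density_cfu_per_cm2: float
    titer_cfu_per_ml: Optional[float]

    def to_dict(self) -> dict:
        return {
            "times_min": list(self.times_min),
            "counts": list(self.counts),
            "mean_diameters_um": list(self.mean_diameters_um),
            "sd_diameters_um": list(self.sd_diameters_um),
            "saturation_time_min": self.saturation_time_min,
            "final_count": self.final_count,
            "density_cfu_per_cm2": self.density_cfu_per_cm2,
            "titer_cfu_per_ml": self.titer_cfu_per_ml,
        }


def build_report(
    regions_by_time: Sequence[tuple[float, Sequence[ColonyRegion]]],
    fov_mm2: float,
    saturation_fraction: float = 0.95,
    sample_volume_ul: Optional[float] = None,
    dilution_factor: float = 1.0,
    max_link_distance_um: float = 15.0,
) -> tuple[TimeSeriesReport, list[ColonyTrack]]:
    """Assemble the full time-series report from per-timepoint regions."""
    tracks = link_tracks(regions_by_time, max_link_distance_um=max_link_distance_um)
    items = sorted(regions_by_time, key=lambda p: p[0])
    times = [t for t, _ in items]
    counts = [sum(1 for r in regs if r.counted) for _, regs in items]
    means, sds = [], []
    for t, regs in items:
        diams = [r.equivalent_diameter_um for r in regs if r.counted]
        means.append(float(np.mean(diams)) if diams else float("nan"))
        sds.append(float(np.std(diams, ddof=1)) if len(diams) > 1 else 0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sat = saturation_time(times, counts, fraction=saturation_fraction) if times else None
    final = counts[-1] if counts else 0
    density = final / (fov_mm2 / 100.0)
    titer = (
        estimate_titer(final, sample_volume_ul, dilution_factor) if sample_volume_ul is not None else None
    )
    report = TimeSeriesReport(
        times_min=tuple(times),
        counts=tuple(counts),
        mean_diameters_um=tuple(means),
        sd_diameters_um=tuple(sds),
        saturation_time_min=sat,
        final_count=final,
        density_cfu_per_cm2=density,
        titer_cfu_per_ml=titer,
    )
    return report, tracks
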