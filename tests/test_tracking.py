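"""Track linking, merge bookkeeping, enumeration statistics, exact U test."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microcolony.segment import ColonyRegion
from microcolony.tracking import (
    build_report,
    density_scale_bound,
    estimate_titer,
    fit_growth_rate,
    link_tracks,
    mann_whitney_exact,
    saturation_time,
    size_distribution,
)
from microcolony.validation import mann_whitney_rank_oracle


def region(label, x, y, d, t, counted=True):
    area = np.pi * (d / 2.0) ** 2
    return ColonyRegion(
        label=label,
        area_um2=area,
        equivalent_diameter_um=d,
        centroid_um=(x, y),
        bbox_um=(x - d / 2, y - d / 2, d, d),
        touches_border=False,
        counted=counted,
        t_min=t,
    )


class TestLinkTracks:
    def test_stationary_colony_gives_one_track(self):
        rbt = [(t, [region(1, 100.0, 100.0, 20.0 + t / 10.0, t)]) for t in [0.0, 20.0, 40.0, 60.0, 80.0]]
        tracks = link_tracks(rbt)
        assert len(tracks) == 1
        assert len(tracks[0].regions) == 5
        assert tracks[0].birth_time_min == 0.0
        assert tracks[0].merged_into is None

    def test_late_appearance_sets_birth_time(self):
        rbt = [
            (200.0, []),
            (240.0, [region(1, 50.0, 50.0, 8.0, 240.0, counted=False)]),
            (280.0, [region(1, 50.0, 50.0, 16.0, 280.0, counted=False)]),
        ]
        tracks = link_tracks(rbt)
        assert len(tracks) == 1
        assert tracks[0].birth_time_min == 240.0

    def test_merge_records_parent_and_survivor(self):
        # two colonies converge; at t=2 a single large region spans both
        rbt = [
            (0.0, [region(1, 0.0, 0.0, 30.0, 0.0), region(2, 60.0, 0.0, 26.0, 0.0)]),
            (20.0, [region(1, 0.0, 0.0, 34.0, 20.0), region(2, 60.0, 0.0, 30.0, 20.0)]),
            (40.0, [region(1, 30.0, 0.0, 80.0, 40.0)]),
        ]
        tracks = link_tracks(rbt)
        assert len(tracks) == 2
        survivor = next(t for t in tracks if t.merged_into is None)
        merged = next(t for t in tracks if t.merged_into is not None)
        # largest-area parent survives (track with the 34-μm region)
        assert survivor.regions[0.0].equivalent_diameter_um == 30.0
        assert merged.merged_into == survivor.track_id
        assert merged.merge_time_min == 40.0
        assert len(survivor.regions) == 3

    def test_conservation_births_equal_active_plus_merged(self):
        rbt = [
            (0.0, [region(1, 0.0, 0.0, 30.0, 0.0), region(2, 60.0, 0.0, 26.0, 0.0), region(3, 200.0, 0.0, 22.0, 0.0)]),
            (20.0, [region(1, 30.0, 0.0, 70.0, 20.0), region(2, 200.0, 0.0, 26.0, 20.0)]),
        ]
        tracks = link_tracks(rbt)
        births = len(tracks)
        merged = sum(1 for t in tracks if t.merged_into is not None)
        active = sum(1 for t in tracks if t.merged_into is None)
        assert births == active + merged == 3

    def test_distant_region_starts_new_track(self):
        rbt = [
            (0.0, [region(1, 0.0, 0.0, 25.0, 0.0)]),
            (20.0, [region(1, 100.0, 100.0, 25.0, 20.0)]),
        ]
        tracks = link_tracks(rbt, max_link_distance_um=15.0)
        assert len(tracks) == 2

    def test_duplicate_labels_rejected(self):
        rbt = [(0.0, [region(1, 0.0, 0.0, 25.0, 0.0), region(1, 50.0, 0.0, 25.0, 0.0)])]
        with pytest.raises(ValueError, match="duplicate"):
            link_tracks(rbt)


class TestSizeDistribution:
    def test_hand_arithmetic(self):
        rbt = [(0.0, [region(i, 100.0 * i, 0.0, d, 0.0) for i, d in enumerate([20.0, 30.0, 40.0])])]
        tracks = link_tracks(rbt)
        dist = size_distribution(tracks, 0.0)
        assert dist.mean_diameter_um == pytest.approx(30.0)
        assert dist.sd_diameter_um == pytest.approx(10.0)
        assert dist.n == 3 and not dist.degenerate

    def test_single_colony_is_flagged_degenerate(self):
        tracks = link_tracks([(0.0, [region(1, 0.0, 0.0, 30.0, 0.0)])])
        dist = size_distribution(tracks, 0.0)
        assert dist.mean_diameter_um == 30.0
        assert dist.sd_diameter_um == 0.0
        assert dist.n == 1 and dist.degenerate

    def test_empty_timepoint_warns(self):
        tracks = link_tracks([(0.0, [region(1, 0.0, 0.0, 30.0, 0.0)])])
        with pytest.warns(UserWarning, match="no counted"):
            dist = size_distribution(tracks, 999.0)
        assert dist.n == 0


class TestSaturationTime:
    def test_worked_example(self):
        t = [0.0, 120.0, 240.0, 360.0, 480.0, 600.0]
        assert saturation_time(t, [0, 0, 10, 48, 50, 50]) == 360.0  # 48 ≥ 0.95·50

    def test_constant_counts_saturate_immediately(self):
        assert saturation_time([0.0, 20.0, 40.0], [7, 7, 7]) == 0.0

    def test_strictly_increasing_saturates_last(self):
        assert saturation_time([0.0, 20.0, 40.0], [1, 10, 100]) == 40.0

    def test_all_zero_counts_undefined(self):
        with pytest.warns(UserWarning, match="zero"):
            assert saturation_time([0.0, 20.0], [0, 0]) is None


class TestEstimateTiter:
    @pytest.mark.parametrize(
        "count,vol,dil,expected",
        [(50, 1.0, 1.0, 5.0e4), (50, 1.0, 100.0, 5.0e6), (0, 2.0, 10.0, 0.0)],
    )
    def test_arithmetic(self, count, vol, dil, expected):
        assert estimate_titer(count, vol, dil) == pytest.approx(expected)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            estimate_titer(10, 0.0)
        with pytest.raises(ValueError):
            estimate_titer(10, 1.0, 0.5)
        with pytest.raises(ValueError):
            estimate_titer(-1, 1.0)


class TestDensityScaleBound:
    def test_identity_and_worked_values(self):
        assert density_scale_bound(10.0, 1000.0, 1000.0) == 10.0
        assert density_scale_bound(10.0, 1000.0, 20.0) == pytest.approx(25000.0)
        assert density_scale_bound(10.0, 1000.0, 500.0) == pytest.approx(40.0)

    @given(base=st.floats(0.1, 100.0), ratio=st.floats(0.01, 100.0))
    @settings(max_examples=100, deadline=None)
    def test_exactly_quadratic_in_diameter_ratio(self, base, ratio):
        bound = density_scale_bound(base, 1000.0, 1000.0 / ratio)
        assert bound == pytest.approx(base * ratio**2, rel=1e-9)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            density_scale_bound(0.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            density_scale_bound(10.0, 1.0, 0.0)


class TestMannWhitneyExact:
    def test_fully_separated_groups(self):
        result = mann_whitney_exact([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert result.u_statistic == 0.0
        assert result.p_value == pytest.approx(0.1)  # 2 of C(6,3)=20 assignments as extreme

    def test_interleaved_groups_are_indistinguishable(self):
        result = mann_whitney_exact([1.0, 4.0], [2.0, 3.0])
        assert result.u_statistic == 2.0  # equals nA·nB/2
        assert result.p_value == 1.0

    def test_identical_multisets_give_p_one(self):
        result = mann_whitney_exact([5.0, 7.0, 7.0, 9.0], [5.0, 7.0, 7.0, 9.0])
        assert result.p_value == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_exact([], [1.0])

    def test_matches_rank_based_oracle_on_200_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            na = int(rng.integers(2, 7))
            nb = int(rng.integers(2, 7))
            a = rng.integers(0, 6, size=na).astype(float)  # small support → frequent ties
            b = rng.integers(0, 6, size=nb).astype(float)
            result = mann_whitney_exact(a, b)
            u_ref, p_ref = mann_whitney_rank_oracle(a, b)
            assert result.u_statistic == pytest.approx(u_ref, abs=1e-12)
            assert result.p_value == pytest.approx(p_ref, abs=1e-12)


class TestFitGrowthRate:
    def test_recovers_slope_of_linear_track(self):
        rbt = [(t, [region(1, 50.0, 50.0, 5.0 + 0.24 * t, t)]) for t in np.arange(0.0, 201.0, 20.0)]
        tracks = link_tracks(rbt)
        assert fit_growth_rate(tracks[0]) == pytest.approx(0.12, rel=1e-9)

    def test_short_track_returns_none(self):
        tracks = link_tracks([(0.0, [region(1, 0.0, 0.0, 20.0, 0.0)])])
        assert fit_growth_rate(tracks[0]) is None


class TestBuildReport:
    def test_counts_saturation_density_titer(self):
        rbt = [
            (0.0, []),
            (20.0, [region(1, 50.0, 50.0, 25.0, 20.0)]),
            (40.0, [region(1, 50.0, 50.0, 30.0, 40.0), region(2, 150.0, 50.0, 22.0, 40.0)]),
            (60.0, [region(1, 50.0, 50.0, 35.0, 60.0), region(2, 150.0, 50.0, 27.0, 60.0)]),
        ]
        report, tracks = build_report(rbt, fov_mm2=25.0, sample_volume_ul=1.0, dilution_factor=100.0)
        assert report.counts == (0, 1, 2, 2)
        assert report.final_count == 2
        assert report.saturation_time_min == 40.0
        assert report.density_cfu_per_cm2 == pytest.approx(2 / 0.25)
        assert report.titer_cfu_per_ml == pytest.approx(2 * 100.0 / 1e-3)
        assert len(tracks) == 2
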