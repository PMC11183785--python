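import numpy as np
import pytest

from cereflow import TubeSpec, make_tube_phantom
from cereflow.flow import (
    AnalysisPlane,
    Branch,
    VesselTree,
    exclude_end_planes,
    exclude_junction_planes,
    extract_centerline,
    flow_conservation_error,
    measure_plane,
    place_analysis_planes,
    quantify_vessels,
    stenosis_profile,
    summarize_vessel,
)
from cereflow.io import SegmentationMask


def _straight_branch(length=10.0, n=101):
    pts = np.zeros((n, 3))
    pts[:, 2] = np.linspace(0.0, length, n)
    tan = np.tile([0.0, 0.0, 1.0], (n, 1))
    return Branch(points=pts, tangents=tan, label="b")


class TestExtractCenterline:
    def test_straight_tube_axis_accuracy(self, straight_tube):
        spec, vol, truth = straight_tube
        tree = extract_centerline(truth.mask)
        assert len(tree.branches) == 1
        assert len(tree.junctions) == 0
        b = tree.branches[0]
        # perpendicular deviation from the true axis < 0.6 voxels
        dev = np.linalg.norm(b.points[:, :2] - spec.start[:2][None], axis=1)
        assert dev.max() < 0.6 * 0.4
        # chain length within 5% of the true tube length
        true_len = np.linalg.norm(spec.end - spec.start)
        assert b.length_mm == pytest.approx(true_len, rel=0.05)
        # consecutive points at most one voxel apart
        steps = np.linalg.norm(np.diff(b.points, axis=0), axis=1)
        assert steps.max() <= np.sqrt(3) * 0.4 + 1e-9
        norms = np.linalg.norm(b.tangents, axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-9)

    def test_bifurcation_topology(self, bifurcation):
        _, truth = bifurcation
        tree = extract_centerline(truth.mask)
        assert len(tree.branches) == 3
        assert len(tree.junctions) == 1
        # junction recovered near the truth junction point
        d = np.linalg.norm(tree.junctions[0] - truth.junctions[0])
        assert d < 2.0

    def test_solid_sphere_degenerates_to_single_short_branch(self):
        z, y, x = np.indices((20, 20, 20))
        ball = (((z - 9.5) ** 2 + (y - 9.5) ** 2 + (x - 9.5) ** 2) <= 36).astype(np.uint8)
        mask = SegmentationMask(labels=ball, spacing=np.ones(3))
        tree = extract_centerline(mask)
        assert len(tree.branches) == 1
        assert len(tree.junctions) == 0
        assert tree.branches[0].length_mm < 6.0  # no elongated structure

    def test_empty_mask_rejected(self):
        mask = SegmentationMask(labels=np.zeros((5, 5, 5), np.uint8),
                                spacing=np.ones(3))
        with pytest.raises(ValueError, match="empty"):
            extract_centerline(mask)


class TestPlanePlacement:
    def test_exact_division_gives_floor_plus_one_planes(self):
        tree = VesselTree(branches=[_straight_branch(10.0)], junctions=[])
        planes = place_analysis_planes(tree, 0.25)
        assert len(planes) == 41

    def test_spacing_beyond_length_gives_single_start_plane(self):
        tree = VesselTree(branches=[_straight_branch(2.0, n=21)], junctions=[])
        planes = place_analysis_planes(tree, 5.0)
        assert len(planes) == 1
        np.testing.assert_allclose(planes[0].center, [0, 0, 0], atol=1e-12)

    def test_normals_unit_and_parallel_to_tangent(self, straight_tube):
        _, _, truth = straight_tube
        tree = extract_centerline(truth.mask)
        planes = place_analysis_planes(tree)
        for p in planes:
            assert np.linalg.norm(p.normal) == pytest.approx(1.0, abs=1e-6)
        # straight tube: tangent is the x axis
        axis = np.array([0.0, 0.0, 1.0])
        cosines = [abs(p.normal @ axis) for p in planes]
        assert np.median(cosines) > 0.999

    def test_zero_exclusion_is_identity(self, bifurcation):
        _, truth = bifurcation
        tree = extract_centerline(truth.mask)
        planes = place_analysis_planes(tree)
        assert exclude_junction_planes(planes, tree, 0.0) == planes

    def test_exclusion_matches_brute_force_count(self, bifurcation):
        _, truth = bifurcation
        tree = extract_centerline(truth.mask)
        planes = place_analysis_planes(tree)
        kept = exclude_junction_planes(planes, tree, 2.0)
        junc = np.stack(tree.junctions)
        n_removed_ref = sum(
            1
            for p in planes
            if np.linalg.norm(junc - p.center, axis=1).min() < 2.0
        )
        assert len(planes) - len(kept) == n_removed_ref
        for p in kept:
            assert np.linalg.norm(junc - p.center, axis=1).min() >= 2.0


class TestMeasurePlane:
    def test_poiseuille_closed_forms(self, straight_tube):
        spec, vol, truth = straight_tube
        plane = AnalysisPlane(
            center=np.array([spec.start[0], spec.start[1], 21.8]),
            normal=np.array([0.0, 0.0, 1.0]),
            branch_label="b", arc_s=0.0,
        )
        m = measure_plane(plane, vol, truth.mask)
        assert m.area_mm2 == pytest.approx(np.pi * 4.0, rel=0.10)
        assert m.mean_flow_mls == pytest.approx(np.pi, rel=0.05)
        assert m.peak_velocity_ms == pytest.approx(0.5, rel=0.05)

    def test_reversed_normal_flips_flow_not_peak(self, straight_tube):
        spec, vol, truth = straight_tube
        kwargs = dict(branch_label="b", arc_s=0.0)
        c = np.array([spec.start[0], spec.start[1], 21.8])
        m_fwd = measure_plane(
            AnalysisPlane(center=c, normal=np.array([0.0, 0.0, 1.0]), **kwargs),
            vol, truth.mask,
        )
        m_rev = measure_plane(
            AnalysisPlane(center=c, normal=np.array([0.0, 0.0, -1.0]), **kwargs),
            vol, truth.mask,
        )
        np.testing.assert_allclose(
            m_rev.flow_per_phase_mls, -m_fwd.flow_per_phase_mls, atol=1e-12
        )
        assert m_rev.peak_velocity_ms == m_fwd.peak_velocity_ms

    def test_zero_velocity_zero_flow_area_unchanged(self, straight_tube):
        spec, vol, truth = straight_tube
        still = vol.replace(velocity=np.zeros_like(vol.velocity))
        plane = AnalysisPlane(
            center=np.array([spec.start[0], spec.start[1], 21.8]),
            normal=np.array([0.0, 0.0, 1.0]), branch_label="b", arc_s=0.0,
        )
        m0 = measure_plane(plane, still, truth.mask)
        m1 = measure_plane(plane, vol, truth.mask)
        assert m0.peak_velocity_ms == 0.0
        np.testing.assert_allclose(m0.flow_per_phase_mls, 0.0)
        assert m0.area_mm2 == m1.area_mm2

    def test_through_plane_peak_equals_speed_for_axial_flow(self, straight_tube):
        spec, vol, truth = straight_tube
        plane = AnalysisPlane(
            center=np.array([spec.start[0], spec.start[1], 21.8]),
            normal=np.array([0.0, 0.0, 1.0]), branch_label="b", arc_s=0.0,
        )
        m_speed = measure_plane(plane, vol, truth.mask, peak_mode="speed")
        m_tp = measure_plane(plane, vol, truth.mask, peak_mode="through-plane")
        # flow is purely axial here, so both definitions coincide
        assert m_tp.peak_velocity_ms == pytest.approx(m_speed.peak_velocity_ms)
        with pytest.raises(ValueError, match="peak_mode"):
            measure_plane(plane, vol, truth.mask, peak_mode="bogus")

    def test_center_outside_mask_rejected(self, straight_tube):
        spec, vol, truth = straight_tube
        plane = AnalysisPlane(
            center=np.array([0.4, 0.4, 21.8]),
            normal=np.array([0.0, 0.0, 1.0]), branch_label="b", arc_s=0.0,
        )
        with pytest.raises(ValueError, match="outside"):
            measure_plane(plane, vol, truth.mask)

    def test_area_error_shrinks_with_finer_in_plane_sampling(self, straight_tube):
        spec, vol, truth = straight_tube
        plane = AnalysisPlane(
            center=np.array([spec.start[0], spec.start[1], 21.8]),
            normal=np.array([0.0, 0.0, 1.0]), branch_label="b", arc_s=0.0,
        )
        errs = [
            abs(measure_plane(plane, vol, truth.mask, oversample=ov).area_mm2
                - np.pi * 4.0)
            for ov in (2, 8)
        ]
        assert errs[1] <= errs[0]

    def test_oblique_tube_measures_match_axis_aligned(self):
        # same tube rotated 30 degrees in-plane: metrics within a few %
        shape, spacing = (40, 70, 70), (0.4, 0.4, 0.4)
        ext = (np.array(shape) - 1) * 0.4
        c = ext / 2
        direction = np.array([0.0, np.sin(np.pi / 6), np.cos(np.pi / 6)])
        spec = TubeSpec(
            start=c - 13.0 * direction, end=c + 13.0 * direction,
            radius_mm=2.0, v_max=0.5, label="tube",
        )
        vol, truth = make_tube_phantom(spec, shape, spacing)
        summaries, _ = quantify_vessels(vol, truth.mask)
        s = summaries[0]
        assert s.median_area_mm2 == pytest.approx(np.pi * 4.0, rel=0.04)
        assert s.median_mean_flow_mls == pytest.approx(np.pi, rel=0.04)
        assert s.median_peak_velocity_ms == pytest.approx(0.5, rel=0.04)


class TestSummaries:
    def test_single_plane_summary_equals_that_plane(self, straight_tube):
        spec, vol, truth = straight_tube
        plane = AnalysisPlane(
            center=np.array([spec.start[0], spec.start[1], 21.8]),
            normal=np.array([0.0, 0.0, 1.0]), branch_label="b", arc_s=0.0,
        )
        m = measure_plane(plane, vol, truth.mask)
        s = summarize_vessel("v", [m])
        assert s.median_area_mm2 == m.area_mm2
        assert s.median_mean_flow_mls == abs(m.mean_flow_mls)
        assert s.n_planes == 1

    def test_median_definition_and_permutation_invariance(self):
        def fake(area):
            return type("M", (), {
                "area_mm2": area, "peak_velocity_ms": 0.1,
                "mean_flow_mls": 1.0,
            })()

        ms = [fake(a) for a in (10.0, 12.0, 20.0)]
        assert summarize_vessel("v", ms).median_area_mm2 == 12.0
        assert (
            summarize_vessel("v", ms[::-1]).median_area_mm2
            == summarize_vessel("v", ms).median_area_mm2
        )

    def test_empty_measurement_list_rejected(self):
        with pytest.raises(ValueError):
            summarize_vessel("v", [])

    def test_stenosed_tube_median_and_minimum_area(self):
        # moderate, wide stenosis: the throat stays resolved (>= 6
        # vox/diameter) and more than half the planes are narrowed, so the
        # median is pulled below the inlet area
        spacing = (0.4, 0.4, 0.4)
        shape = (24, 24, 110)
        c = (np.array(shape) - 1) / 2 * 0.4
        spec = TubeSpec(
            start=[c[0], c[1], 2.4], end=[c[0], c[1], 41.0],
            radius_mm=2.0, v_max=0.5, stenosis_grade=0.4,
            stenosis_width_mm=8.0, label="s",
        )
        vol, truth = make_tube_phantom(spec, shape, spacing)
        summaries, per_branch = quantify_vessels(vol, truth.mask)
        s = summaries[0]
        assert s.median_area_mm2 < np.pi * 4.0
        min_area = min(m.area_mm2 for ms in per_branch.values() for m in ms)
        r_min = 2.0 * (1 - 0.4)
        assert min_area == pytest.approx(np.pi * r_min**2, rel=0.15)


class TestFlowConservation:
    def test_arithmetic_cases(self):
        assert flow_conservation_error([4.0], [4.0]) == 0.0
        assert flow_conservation_error([4.0], [3.0]) == pytest.approx(0.25)
        assert flow_conservation_error([2.0, 2.0], [2.8, 1.2]) == pytest.approx(0.0)

    def test_zero_inflow_rejected(self):
        with pytest.raises(ValueError):
            flow_conservation_error([0.0], [1.0])

    def test_bifurcation_pipeline_fce_below_discretization_bound(self, bifurcation):
        vol, truth = bifurcation
        summaries, _ = quantify_vessels(vol, truth.mask)
        assert len(summaries) == 3
        by_area = sorted(summaries, key=lambda s: -s.median_area_mm2)
        fce = flow_conservation_error(
            [by_area[0].median_mean_flow_mls],
            [s.median_mean_flow_mls for s in by_area[1:]],
        )
        assert fce < 0.05


@pytest.fixture(scope="module")
def profile(stenosed_tube):
    spec, vol, truth = stenosed_tube
    tree = extract_centerline(truth.mask)
    planes = exclude_end_planes(place_analysis_planes(tree), tree)
    ms = []
    for p in planes:
        try:
            ms.append(measure_plane(p, vol, truth.mask))
        except ValueError:
            continue
    ms.sort(key=lambda m: m.plane.arc_s)
    return spec, ms


class TestStenosisProfile:
    def test_minimum_area_located_at_stenosis_center(self, profile):
        spec, ms = profile
        prof = stenosis_profile(ms)
        true_z = 0.5 * (spec.start[2] + spec.end[2])
        z_at_min = ms[int(np.argmin(prof["area_mm2"]))].plane.center[2]
        assert abs(z_at_min - true_z) <= 1.0

    def test_velocity_peaks_where_area_pinches(self, profile):
        from scipy.stats import spearmanr

        spec, ms = profile
        prof = stenosis_profile(ms)
        # region of interest around the stenosis (+/- 3 sigma), as in a
        # clinical per-lesion profile analysis
        true_z = 0.5 * (spec.start[2] + spec.end[2])
        z = np.array([m.plane.center[2] for m in ms])
        sel = np.abs(z - true_z) <= 3 * spec.stenosis_width_mm
        rho = spearmanr(
            1.0 / prof["area_mm2"][sel], prof["peak_velocity_ms"][sel]
        ).statistic
        assert rho > 0.9

    def test_roi_flow_curve_has_one_sample_per_phase(self, profile):
        _, ms = profile
        prof = stenosis_profile(ms, roi_mm=(0.0, ms[-1].plane.arc_s))
        assert len(prof["roi_flow_curve_mls"]) == len(ms[0].flow_per_phase_mls)

    def test_empty_roi_rejected(self, profile):
        _, ms = profile
        with pytest.raises(ValueError, match="ROI"):
            stenosis_profile(ms, roi_mm=(1e3, 2e3))
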