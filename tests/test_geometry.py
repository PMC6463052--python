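"""Contour measures, volumes, area-motion, and hex tube meshes."""

import numpy as np
import pytest

from oftflow import geometry
from oftflow.geometry import (
    AreaMotionMatrix,
    CrossSectionSeries,
    MeshError,
    area_motion,
    build_mesh,
    centerline_length,
    contour_area,
    contour_centroid,
    hex_jacobian_min,
    mesh_volume,
    slab_volume,
)
from oftflow.phantom import PhantomConfig, PhantomKinematics
from oftflow.segment import Contour

from conftest import circle_contour, cylinder_series


def truth_series(config, n_phases=20) -> CrossSectionSeries:
    """Contour grid straight from the phantom's analytic wall radius."""
    kin = PhantomKinematics(config)
    th = np.arange(64) * 2 * np.pi / 64
    contours = []
    for k in range(config.n_slices):
        s = k / (config.n_slices - 1)
        row = []
        for t in range(n_phases):
            R = float(kin.radius(s, t / n_phases))
            if R < 3 * config.pixel_size_mm:
                row.append(Contour(np.empty((0, 2)), slice_index=k,
                                   phase_index=t, is_closed_lumen=True))
            else:
                row.append(Contour(
                    np.column_stack([R * np.cos(th), R * np.sin(th)]),
                    slice_index=k, phase_index=t))
        contours.append(row)
    return CrossSectionSeries(contours=contours,
                              slice_spacing_mm=config.slice_spacing_um / 1000)


class TestContourArea:
    def test_unit_square(self):
        sq = Contour(np.array(
            [[0, 0], [1, 0], [1, 1], [0, 1], [0.5, 0.5]] ).repeat(2, axis=0)[:8])
        # build a proper 8-vertex square traversal instead
        sq = Contour(np.array(
            [[0, 0], [0.5, 0], [1, 0], [1, 0.5], [1, 1], [0.5, 1], [0, 1],
             [0, 0.5]]))
        assert contour_area(sq) == pytest.approx(1.0)

    def test_64gon_close_to_circle(self):
        c = circle_contour(0.2)
        assert contour_area(c) == pytest.approx(np.pi * 0.04, rel=0.002)

    def test_closed_lumen_is_zero(self):
        c = Contour(np.empty((0, 2)), is_closed_lumen=True)
        assert contour_area(c) == 0.0

    def test_centroid_of_offset_circle(self):
        c = circle_contour(0.1, cx=0.3, cy=-0.2)
        assert contour_centroid(c) == pytest.approx([0.3, -0.2], abs=1e-9)


class TestSlabVolume:
    def test_cylinder_within_one_percent(self):
        series = cylinder_series(radius=0.2, n_slices=51, spacing=0.02)
        assert slab_volume(series, 0) == pytest.approx(np.pi * 0.04 * 1.0,
                                                       rel=0.01)

    def test_cone_matches_frustum(self):
        contours = [[circle_contour(0.1 + 0.2 * k / 50, slice_index=k)]
                    for k in range(51)]
        series = CrossSectionSeries(contours=contours, slice_spacing_mm=0.02)
        frustum = np.pi / 3 * (0.1**2 + 0.1 * 0.3 + 0.3**2)
        assert slab_volume(series, 0) == pytest.approx(frustum, rel=0.02)

    def test_additive_over_slice_ranges(self):
        series = cylinder_series(radius=0.15, n_slices=21)
        sub_a = CrossSectionSeries(series.contours[:11], series.slice_spacing_mm)
        sub_b = CrossSectionSeries(series.contours[10:], series.slice_spacing_mm)
        total = slab_volume(series, 0)
        # split shares the middle slice: half-gaps at the cut add up
        assert slab_volume(sub_a, 0) + slab_volume(sub_b, 0) == pytest.approx(
            total, rel=1e-9)


class TestCenterline:
    def test_straight_tube_exact(self):
        series = cylinder_series(n_slices=51, spacing=0.02)
        assert centerline_length(series, 0) == pytest.approx(1.0, abs=1e-12)

    def test_quarter_circle_arc(self):
        """Centroids tracing a quarter circle in the (x, z) plane.

        Slices are parallel planes at uniform z spacing, so the bend is
        encoded by in-plane centroid drift: x = R(1 - cos th) with
        z = R sin th covers th in [0, pi/2].
        """
        R, n = 0.64, 41
        dz = R / (n - 1)
        contours = []
        for k in range(n):
            th = np.arcsin(min(k * dz / R, 1.0))
            contours.append([circle_contour(
                0.05, cx=R * (1 - np.cos(th)), cy=0.0, slice_index=k)])
        series = CrossSectionSeries(contours=contours, slice_spacing_mm=dz)
        assert centerline_length(series, 0) == pytest.approx(
            np.pi * R / 2, rel=0.02)

    def test_invariant_under_rigid_translation(self):
        series = cylinder_series(n_slices=11)
        moved = CrossSectionSeries(
            [[Contour(c.vertices + np.array([0.37, -1.2]),
                      slice_index=c.slice_index)]
             for row in series.contours for c in row],
            series.slice_spacing_mm)
        assert centerline_length(moved, 0) == pytest.approx(
            centerline_length(series, 0), abs=1e-12)

    def test_defaults_to_minimum_volume_phase(self):
        cfg = PhantomConfig(n_slices=11, image_depth_px=16, image_width_px=16)
        series = truth_series(cfg, n_phases=10)
        vols = [slab_volume(series, t) for t in range(10)]
        assert centerline_length(series) == pytest.approx(
            centerline_length(series, int(np.argmin(vols))))


class TestAreaMotion:
    def test_static_tube_constant_in_time(self):
        cfg = PhantomConfig(pulsation_amplitude=0.0, cushion_depth=0.0,
                            n_slices=9, image_depth_px=16, image_width_px=16)
        mat = area_motion(truth_series(cfg, 12))
        assert np.allclose(np.ptp(mat.values, axis=1), 0.0, atol=1e-12)

    def test_traveling_wave_slope_recovered(self):
        cfg = PhantomConfig(pulsation_amplitude=0.25, cushion_depth=0.0,
                            wave_speed=2.0, n_slices=21,
                            image_depth_px=16, image_width_px=16)
        mat = area_motion(truth_series(cfg, 100))
        assert mat.phase_lag_slope == pytest.approx(1.0 / cfg.wave_speed,
                                                    rel=0.05)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            AreaMotionMatrix(values=np.array([[-1.0]]))


class TestBuildMesh:
    def test_cylinder_positive_jacobians_and_volume(self, cylinder_mesh):
        assert hex_jacobian_min(cylinder_mesh) > 0
        body = mesh_volume(cylinder_mesh, include_extensions=False)
        assert body == pytest.approx(np.pi * 0.04 * 1.0, rel=0.01)

    def test_boundary_tags_partition_boundary(self, cylinder_mesh):
        from collections import Counter
        mesh = cylinder_mesh
        faces = Counter()
        FACE = [(0, 1, 2, 3), (4, 5, 6, 7), (0, 1, 5, 4), (1, 2, 6, 5),
                (2, 3, 7, 6), (3, 0, 4, 7)]
        for h in mesh.hexes:
            for f in FACE:
                faces[frozenset(h[list(f)])] += 1
        boundary = {f for f, c in faces.items() if c == 1}
        tagged = [frozenset(q) for q in np.vstack(
            [mesh.inlet_quads, mesh.outlet_quads, mesh.wall_quads])]
        assert len(tagged) == len(set(tagged))  # no face tagged twice
        assert set(tagged) == boundary

    def test_refinement_changes_volume_below_half_percent(self):
        series = cylinder_series(radius=0.18, n_slices=31)
        coarse = build_mesh(series, 0, 10, 16, 3, extension_length_factor=0.5)
        fine = build_mesh(series, 0, 20, 32, 6, extension_length_factor=0.5)
        v0 = mesh_volume(coarse)
        v1 = mesh_volume(fine)
        assert abs(v1 - v0) / v0 < 0.005

    def test_mesh_volume_matches_slab_within_two_percent(self):
        cfg = PhantomConfig(n_slices=21, image_depth_px=16, image_width_px=16)
        series = truth_series(cfg, 10)
        phase = 2
        sv = slab_volume(series, phase)
        mesh = build_mesh(series, phase, 20, 16, 3)
        assert mesh_volume(mesh) == pytest.approx(sv, rel=0.02)

    def test_closed_slice_refused(self):
        cfg = PhantomConfig(n_slices=11, cushion_depth=1.0,
                            image_depth_px=16, image_width_px=16)
        series = truth_series(cfg, 16)
        closed = series.closed_mask()
        t = int(np.argwhere(closed.any(axis=0))[0, 0])
        with pytest.raises(MeshError):
            build_mesh(series, t, 10, 16, 3)

    def test_element_count_scales_to_paper_magnitude(self):
        """Default resolutions give O(10^3)-O(10^4) cells and the knobs
        reach the tens-of-thousands scale used for the real organ."""
        series = cylinder_series(n_slices=31)
        small = build_mesh(series, 0, 12, 16, 3, extension_length_factor=0.5)
        big = build_mesh(series, 0, 80, 32, 10, extension_length_factor=0.5)
        assert 500 < small.n_elements < 10_000
        assert big.n_elements > 30_000
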