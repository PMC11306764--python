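"""TPS patch fitting, triangulation and Heron-formula areas."""

import warnings

import numpy as np
import pytest

import suturemorph as sm
from suturemorph.surface import (
    DegeneratePatch,
    fit_tps_patch,
    surface_area_heron,
    total_suture_area,
    triangulate_patch,
)
from suturemorph.types import TriangulatedSurface, ValidationError


def _grid(n=8, span=10.0):
    x = np.linspace(-span, span, n)
    gx, gy = np.meshgrid(x, x)
    return np.column_stack([gx.ravel(), gy.ravel()])


class TestTPS:
    def test_plane_reproduced_exactly(self):
        uv = _grid(6)
        z = 2 * uv[:, 0] + 3 * uv[:, 1] + 1
        tps = fit_tps_patch(np.column_stack([uv, z]), "XY")
        probe = np.array([[1.7, -4.2], [0.0, 0.0], [-8.3, 9.9]])
        np.testing.assert_allclose(
            tps(probe), 2 * probe[:, 0] + 3 * probe[:, 1] + 1, atol=1e-8)

    def test_interpolates_input_points(self, rng):
        uv = _grid(7)
        z = np.sin(uv[:, 0]) * np.cos(uv[:, 1])
        tps = fit_tps_patch(np.column_stack([uv, z]), "XY")
        assert np.abs(tps(uv) - z).max() < 1e-9

    def test_heldout_residual_decreases_with_density(self):
        probe = _grid(15, span=8.0)
        truth = np.sin(probe[:, 0]) * np.cos(probe[:, 1])
        errs = []
        for n in (6, 10, 18):
            uv = _grid(n, span=10.0)
            z = np.sin(uv[:, 0]) * np.cos(uv[:, 1])
            tps = fit_tps_patch(np.column_stack([uv, z]), "XY")
            errs.append(np.abs(tps(probe) - truth).max())
        assert errs[0] > errs[1] > errs[2]

    def test_collinear_projections_rejected(self):
        pts = np.column_stack([np.linspace(0, 1, 8), np.zeros(8),
                               np.linspace(0, 2, 8)])
        with pytest.raises(DegeneratePatch, match="collinear"):
            fit_tps_patch(pts, "XY")

    def test_duplicate_projections_merged_by_averaging(self):
        pts = np.array([[0, 0, 1.0], [0, 0, 3.0], [1, 0, 0], [0, 1, 0],
                        [1, 1, 0]])
        tps = fit_tps_patch(pts, "XY")
        assert tps([[0, 0]])[0] == pytest.approx(2.0, abs=1e-8)


class TestTriangulate:
    def test_mean_edge_tracks_target(self):
        square = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        pts = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0], [0.5, 0.5, 0]])
        tps = fit_tps_patch(pts, "XY")
        tri = triangulate_patch(tps, square, target_edge=0.1)
        assert 0.05 <= tri.mean_edge_length() <= 0.15

    def test_planar_region_stays_coplanar(self):
        square = np.array([[0, 0], [2, 0], [2, 2], [0, 2]], float)
        pts = np.array([[0, 0, 5], [2, 0, 5], [2, 2, 5], [0, 2, 5], [1, 1, 5]])
        tps = fit_tps_patch(pts, "XY")
        tri = triangulate_patch(tps, square, target_edge=0.2)
        assert np.abs(tri.vertices[:, 2] - 5).max() < 1e-9

    def test_default_edge_near_reference_value(self, semilandmarks, partition):
        """At defaults the mean 3D triangle edge sits near 0.3 mm."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = total_suture_area(semilandmarks, partition,
                                    target_edge=0.3, keep_surfaces=True)
        edges = [t.mean_edge_length() for ts in res.surfaces.values() for t in ts]
        assert 0.15 <= np.mean(edges) <= 0.45


class TestHeron:
    def test_3_4_5_triangle(self):
        tri = TriangulatedSurface(
            np.array([[0, 0, 0], [3, 0, 0], [3, 4, 0]], float), [[0, 1, 2]])
        area, excluded = surface_area_heron(tri)
        assert area == pytest.approx(6.0)
        assert excluded == 0

    def test_unit_square_two_triangles(self):
        tri = TriangulatedSurface(
            np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], float),
            [[0, 1, 2], [0, 2, 3]])
        assert surface_area_heron(tri)[0] == pytest.approx(1.0)

    def test_degenerate_triangle_excluded_with_warning(self):
        tri = TriangulatedSurface(
            np.array([[0, 0, 0], [1, 0, 0], [2.0000001, 0, 1e-9]], float),
            [[0, 1, 2]])
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            area, excluded = surface_area_heron(tri)
        # nearly-collinear: either an exact zero clamp or an exclusion
        assert area < 1e-6
        assert excluded in (0, 1)

    def test_spherical_cap_area(self):
        R, h = 40.0, 6.0
        rc = np.sqrt(R * R - (R - h) ** 2)
        th = np.linspace(0, 2 * np.pi, 80, endpoint=False)
        rr = np.linspace(0, rc, 14)[1:]
        uv = np.vstack([[0.0, 0.0]] + [
            np.column_stack([r * np.cos(th), r * np.sin(th)]) for r in rr])
        z = np.sqrt(R * R - (uv ** 2).sum(axis=1)) - (R - h)
        tps = fit_tps_patch(np.column_stack([uv, z]), "XY")
        ring = np.column_stack([rc * np.cos(th), rc * np.sin(th)])
        tri = triangulate_patch(tps, ring, target_edge=0.3)
        area, _ = surface_area_heron(tri)
        assert area == pytest.approx(2 * np.pi * R * h, rel=0.01)


class TestTotalArea:
    def test_flat_fixture_matches_analytic_footprint(self):
        """Rhombic fontanelle plus straight strips, all planar: total TPS
        area must match d1 d2 / 2 + sum(length x width)."""
        d1, d2 = 30.0, 25.0
        rhombus = np.array([[d1 / 2, 0], [0, d2 / 2], [-d1 / 2, 0], [0, -d2 / 2]])
        strips = [(50.0, 1.5), (80.0, 5.0)]
        support = np.vstack([rhombus, [[3, 2], [-4, 1], [100, 50], [-100, -50],
                                       [120, 0], [0, 90]]])
        tps = fit_tps_patch(np.column_stack([support, np.zeros(len(support))]),
                            "XY")
        total = 0.0
        regions = [rhombus]
        for i, (L, w) in enumerate(strips):
            x0 = 40.0 + 20 * i
            regions.append(np.array([[x0, 0], [x0 + L, 0],
                                     [x0 + L, w], [x0, w]]))
        for reg in regions:
            tri = triangulate_patch(tps, reg, target_edge=0.3)
            total += surface_area_heron(tri)[0]
        expected = d1 * d2 / 2 + sum(L * w for L, w in strips)
        assert total == pytest.approx(expected, rel=0.02)

    def test_five_patches_reported(self, semilandmarks, partition):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = total_suture_area(semilandmarks, partition, target_edge=0.6)
        assert set(res.per_patch) == {"superior", "anterior", "posterior",
                                      "lateral_left", "lateral_right"}
        assert not res.partial
        assert res.total == pytest.approx(
            sum(v for v in res.per_patch.values()))

    def test_similarity_scaling_squares_area(self, semilandmarks, partition):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            base = total_suture_area(semilandmarks, partition, target_edge=0.6)
            scaled_sl = semilandmarks.with_points(semilandmarks.points * 1.7)
            scaled = total_suture_area(scaled_sl, partition,
                                       target_edge=0.6 * 1.7)
        assert scaled.total == pytest.approx(base.total * 1.7 ** 2, rel=0.01)

    def test_refinement_converges(self, semilandmarks, partition):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            areas = [total_suture_area(semilandmarks, partition,
                                       target_edge=e).total
                     for e in (1.2, 0.6, 0.3)]
        d1 = abs(areas[1] - areas[0])
        d2 = abs(areas[2] - areas[1])
        assert d2 < d1

    def test_self_intersecting_region_rejected(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0], [0.5, 0.2, 0]])
        tps = fit_tps_patch(pts, "XY")
        bowtie = np.array([[0, 0], [1, 1], [1, 0], [0, 1]], float)
        tri = triangulate_patch(tps, bowtie, target_edge=0.1)
        area, _ = surface_area_heron(tri)
        # a bowtie is repaired to its largest lobe, never a full square
        assert area < 0.5
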