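"""Thin-plate-spline surface reconstruction and Heron-formula areas.

The suture/fontanelle system is reconstructed as five height-field
patches -- superior over the X-Y plane, left/right lateral over Y-Z,
anterior and posterior over Z-X.  Each patch's semilandmarks are fitted
with an interpolating thin-plate spline h(u, v) (kernel r^2 log r with
an affine tail, zero smoothing by default); every part footprint is then
densely sampled inside its boundary polygon, Delaunay-triangulated in
the base plane, lifted through the spline and summed with Heron's
formula  S = sum_i sqrt(s(s-a)(s-b)(s-c)),  s = (a+b+c)/2.

In-plane sampling spacing is reduced by the patch's mean metric factor
sqrt(1 + |grad h|^2 / 2) so that the mean 3D triangle edge tracks the
requested target (default 0.3 mm).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.interpolate import RBFInterpolator
from scipy.spatial import Delaunay
from shapely.geometry import Polygon

from .types import (
    PartRange,
    SemilandmarkSet,
    SuturePartition,
    TriangulatedSurface,
    ValidationError,
)
from .borders import side_polyline

#: base-plane axis selection: (u axis, v axis, height axis)
_PLANES = {"XY": (0, 1, 2), "YZ": (1, 2, 0), "ZX": (2, 0, 1)}


class DegeneratePatch(ValidationError):
    pass


@dataclass
class TPSPatch:
    """An interpolating TPS height field over one base plane."""

    base_plane: str
    interp: RBFInterpolator
    uv: np.ndarray
    h: np.ndarray

    def __call__(self, uv: np.ndarray) -> np.ndarray:
        return self.interp(np.atleast_2d(np.asarray(uv, dtype=float)))

    def lift(self, uv: np.ndarray) -> np.ndarray:
        """Map base-plane points to 3D in the original coordinate order."""
        uv = np.atleast_2d(np.asarray(uv, dtype=float))
        h = self(uv)
        iu, iv, ih = _PLANES[self.base_plane]
        out = np.empty((len(uv), 3))
        out[:, iu] = uv[:, 0]
        out[:, iv] = uv[:, 1]
        out[:, ih] = h
        return out

    def gradient_norm(self, uv: np.ndarray, eps: float = 1e-4) -> np.ndarray:
        uv = np.atleast_2d(uv)
        du = (self(uv + [eps, 0]) - self(uv - [eps, 0])) / (2 * eps)
        dv = (self(uv + [0, eps]) - self(uv - [0, eps])) / (2 * eps)
        return np.hypot(du, dv)


def project(points: np.ndarray, base_plane: str) -> tuple[np.ndarray, np.ndarray]:
    """Split 3D points into (uv, h) for the given base plane."""
    iu, iv, ih = _PLANES[base_plane]
    pts = np.asarray(points, dtype=float)
    return pts[:, [iu, iv]], pts[:, ih]


def fit_tps_patch(
    points: np.ndarray,
    base_plane: str = "XY",
    smoothing: float = 0.0,
    duplicate_tol: float = 1e-6,
) -> TPSPatch:
    """Fit an interpolating thin-plate spline height field.

    Points whose base-plane projections coincide (within
    ``duplicate_tol``) are merged by averaging their heights; collinear
    projections raise ``DegeneratePatch``.
    """
    if base_plane not in _PLANES:
        raise ValueError(f"base_plane must be one of {sorted(_PLANES)}")
    uv, h = project(points, base_plane)
    if len(uv) < 4:
        raise DegeneratePatch("degenerate patch: need >= 4 points")
    # merge duplicate projections
    key = np.round(uv / duplicate_tol).astype(np.int64)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    if counts.max() > 1:
        uv_m = np.zeros((len(counts), 2))
        h_m = np.zeros(len(counts))
        np.add.at(uv_m, inv, uv)
        np.add.at(h_m, inv, h)
        uv, h = uv_m / counts[:, None], h_m / counts
    centered = uv - uv.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(uv).max())) < 2:
        raise DegeneratePatch("degenerate patch: collinear projections")
    interp = RBFInterpolator(uv, h, kernel="thin_plate_spline", smoothing=smoothing)
    return TPSPatch(base_plane, interp, uv, h)


def _polygon(boundary_uv: np.ndarray) -> Polygon:
    poly = Polygon(boundary_uv)
    if not poly.is_valid:
        poly = poly.buffer(0)
    if poly.is_empty or poly.area <= 0:
        raise ValidationError("footprint polygon is empty or self-intersecting")
    if poly.geom_type == "MultiPolygon":
        poly = max(poly.geoms, key=lambda g: g.area)
    return poly


def triangulate_patch(
    tps: TPSPatch,
    region: np.ndarray | Polygon,
    target_edge: float = 0.3,
) -> TriangulatedSurface:
    """Sample a footprint region, triangulate in-plane and lift to 3D.

    ``region`` is a simple boundary polygon in the patch's base plane.
    The mean 3D edge length of the result is controlled to track
    ``target_edge``.
    """
    poly = region if isinstance(region, Polygon) else _polygon(np.asarray(region))
    minx, miny, maxx, maxy = poly.bounds

    # estimate the surface metric to convert the 3D edge target to in-plane
    probe = np.linspace([minx, miny], [maxx, maxy], 7)
    gx, gy = np.meshgrid(probe[:, 0], probe[:, 1])
    guv = np.column_stack([gx.ravel(), gy.ravel()])
    inside = shapely.contains_xy(poly, guv[:, 0], guv[:, 1])
    sample = guv[inside] if inside.any() else np.array(poly.representative_point().coords)
    grad = tps.gradient_norm(sample)
    metric = float(np.sqrt(1.0 + 0.5 * np.mean(grad ** 2)))
    # uniform triangular lattice with spacing d has mean edge d
    spacing = target_edge / metric

    xs = np.arange(minx - spacing, maxx + spacing, spacing)
    ys = np.arange(miny - spacing, maxy + spacing, spacing * np.sqrt(3) / 2)
    gx, gy = np.meshgrid(xs, ys)
    gx[1::2] += spacing / 2          # staggered rows -> near-equilateral cells
    grid = np.column_stack([gx.ravel(), gy.ravel()])
    keep = shapely.contains_xy(poly, grid[:, 0], grid[:, 1])
    interior = grid[keep]

    boundary = np.asarray(poly.exterior.coords)[:-1]
    bnd_dense = _densify_closed(boundary, spacing)
    uv = np.vstack([bnd_dense, interior]) if len(interior) else bnd_dense
    if len(uv) < 3:
        raise ValidationError("footprint too small to triangulate at this spacing")

    tri = Delaunay(uv)
    simplices = tri.simplices
    # drop triangles outside the (possibly non-convex) footprint
    cent = uv[simplices].mean(axis=1)
    inside = shapely.contains_xy(poly.buffer(1e-9 * max(1.0, spacing)), cent[:, 0], cent[:, 1])
    simplices = simplices[inside]
    # drop in-plane slivers
    v = uv[simplices]
    e1 = v[:, 1] - v[:, 0]
    e2 = v[:, 2] - v[:, 0]
    area2 = np.abs(e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0])
    simplices = simplices[area2 > 1e-12 * spacing ** 2]
    if len(simplices) == 0:
        raise ValidationError("triangulation produced no interior triangles")

    vertices = tps.lift(uv)
    return TriangulatedSurface(vertices, simplices)


def _densify_closed(boundary: np.ndarray, spacing: float) -> np.ndarray:
    """Resample a closed polygon boundary at roughly uniform spacing."""
    closed = np.vstack([boundary, boundary[0]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    n = max(len(boundary), int(np.ceil(s[-1] / spacing)))
    t = np.linspace(0, s[-1], n, endpoint=False)
    return np.column_stack([np.interp(t, s, closed[:, d]) for d in range(2)])


def surface_area_heron(tri: TriangulatedSurface) -> tuple[float, int]:
    """Total Heron area (mm^2) and the count of excluded degenerate triangles."""
    abc = tri.side_lengths()
    s = abc.sum(axis=1) / 2.0
    arg = s * (s - abc[:, 0]) * (s - abc[:, 1]) * (s - abc[:, 2])
    bad = arg < -1e-12
    n_bad = int(bad.sum())
    if n_bad:
        warnings.warn(f"excluded {n_bad} degenerate triangles from Heron sum")
    return float(np.sqrt(np.clip(arg, 0.0, None)).sum()), n_bad


# ------------------------------------------------------- full-subject area

#: patch name -> (base plane, part names or (part, branch-side) selectors)
PATCH_PLANES = {
    "superior": "XY",
    "anterior": "ZX",
    "posterior": "ZX",
    "lateral_right": "YZ",
    "lateral_left": "YZ",
}


@dataclass
class AreaResult:
    total: float
    per_patch: dict[str, float | None]
    partial: bool
    degenerate_triangles: int
    surfaces: dict[str, list[TriangulatedSurface]] = field(default_factory=dict)


def _strip_polygon(sl: SemilandmarkSet, a: PartRange, b: PartRange) -> np.ndarray:
    """Boundary of a suture strip: side A forward, then back along B.

    Side B is oriented so the loop closes without crossing (its first
    point joins side A's last point).
    """
    A = side_polyline(sl, a)
    B = side_polyline(sl, b)
    if np.linalg.norm(B[0] - A[-1]) > np.linalg.norm(B[-1] - A[-1]):
        B = B[::-1]
    return np.vstack([A, B])


def _loop_polygon(sl: SemilandmarkSet, ranges: list[PartRange], plane: str) -> np.ndarray:
    """Fontanelle footprint: boundary points ordered by angle about the
    centroid in the patch projection (fontanelle footprints are convex)."""
    pts = np.vstack([side_polyline(sl, r) for r in ranges])
    uv, _ = project(pts, plane)
    c = uv.mean(axis=0)
    order = np.argsort(np.arctan2(uv[:, 1] - c[1], uv[:, 0] - c[0]))
    return pts[order]


def patch_footprints(
    sl: SemilandmarkSet, partition: SuturePartition
) -> dict[str, list[np.ndarray]]:
    """3D boundary loops of every part footprint, grouped by patch.

    Default membership: superior = metopic + anterior fontanelle +
    sagittal + posterior fontanelle; anterior = coronal branches;
    posterior = lambdoid branches; each lateral side = its squamosal
    branch plus sphenoidal and mastoid fontanelles.  Every semilandmark
    feeds exactly one patch, so patch areas sum without double counting.
    """
    p = partition.parts
    foot: dict[str, list[np.ndarray]] = {name: [] for name in PATCH_PLANES}

    foot["superior"].append(_strip_polygon(sl, *p["metopic"][:2]))
    foot["superior"].append(_loop_polygon(sl, p["anterior_fontanelle"], "XY"))
    foot["superior"].append(_strip_polygon(sl, *p["sagittal"][:2]))
    foot["superior"].append(_loop_polygon(sl, p["posterior_fontanelle"], "XY"))

    foot["anterior"].append(_strip_polygon(sl, *p["coronal"][0:2]))
    foot["anterior"].append(_strip_polygon(sl, *p["coronal"][2:4]))
    foot["posterior"].append(_strip_polygon(sl, *p["lambdoid"][0:2]))
    foot["posterior"].append(_strip_polygon(sl, *p["lambdoid"][2:4]))

    foot["lateral_right"].append(_strip_polygon(sl, *p["squamosal"][0:2]))
    foot["lateral_right"].append(_loop_polygon(sl, p["sphenoidal_fontanelle"][:3], "YZ"))
    foot["lateral_right"].append(_loop_polygon(sl, p["mastoid_fontanelle"][:3], "YZ"))
    foot["lateral_left"].append(_strip_polygon(sl, *p["squamosal"][2:4]))
    foot["lateral_left"].append(_loop_polygon(sl, p["sphenoidal_fontanelle"][3:], "YZ"))
    foot["lateral_left"].append(_loop_polygon(sl, p["mastoid_fontanelle"][3:], "YZ"))
    return foot


def total_suture_area(
    sl: SemilandmarkSet,
    partition: SuturePartition,
    target_edge: float = 0.3,
    keep_surfaces: bool = False,
) -> AreaResult:
    """Reconstruct the five patches and sum their Heron areas.

    A degenerate patch is reported as missing and the total flagged
    partial instead of failing the subject.
    """
    footprints = patch_footprints(sl, partition)
    per_patch: dict[str, float | None] = {}
    surfaces: dict[str, list[TriangulatedSurface]] = {}
    total = 0.0
    partial = False
    n_bad = 0
    for patch, plane in PATCH_PLANES.items():
        loops = footprints[patch]
        try:
            pts = np.vstack(loops)
            tps = fit_tps_patch(pts, plane)
            area = 0.0
            tris = []
            for loop in loops:
                uv, _ = project(loop, plane)
                tri = triangulate_patch(tps, uv, target_edge=target_edge)
                a, bad = surface_area_heron(tri)
                area += a
                n_bad += bad
                tris.append(tri)
            per_patch[patch] = area
            total += area
            if keep_surfaces:
                surfaces[patch] = tris
        except ValidationError as exc:
            warnings.warn(f"patch {patch!r} degenerate: {exc}")
            per_patch[patch] = None
            partial = True
    return AreaResult(total, per_patch, partial, n_bad, surfaces)


def export_patches(result: AreaResult, path, file_type: str = "obj") -> None:
    """Optional QC export of reconstructed patches (requires trimesh)."""
    import trimesh

    meshes = []
    for tris in result.surfaces.values():
        for t in tris:
            meshes.append(trimesh.Trimesh(vertices=t.vertices, faces=t.triangles))
    trimesh.util.concatenate(meshes).export(path, file_type=file_type)
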