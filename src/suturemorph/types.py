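"""Domain types shared across the suture-morphometry pipeline.

All coordinates are millimetres in a right-handed frame with
X = left -> right, Y = posterior -> anterior, Z = inferior -> superior
(the cranial vault is a height field over X-Y in this frame).

Border curves follow a fixed seven-border topology:

* borders 1/2 -- right/left frontal-bone medial edges, starting at the
  nasion, running up the metopic suture, along the anterior-fontanelle
  edge and down the anterior side of the coronal suture;
* borders 3/4 -- right/left parietal-bone edges, open loops starting and
  ending at the parietal corner point (posterior corner of the anterior
  fontanelle): sagittal edge, posterior-fontanelle edge, lambdoid edge,
  mastoid-fontanelle edge, squamosal edge, sphenoidal-fontanelle edge,
  coronal edge, anterior-fontanelle posterior edge;
* borders 5/6 -- right/left temporal superior edges (squamosal inferior
  side plus sphenoidal/mastoid fontanelle stubs);
* border 7 -- occipital superior edge from right asterion through the
  posterior fontanelle to left asterion.

Default semilandmark counts per border are (100, 100, 200, 200, 50, 50,
100), 800 in total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_COUNTS: tuple[int, ...] = (100, 100, 200, 200, 50, 50, 100)
N_BORDERS = 7

#: canonical part names, in reporting order
PART_NAMES: tuple[str, ...] = (
    "metopic",
    "anterior_fontanelle",
    "sagittal",
    "posterior_fontanelle",
    "coronal",
    "squamosal",
    "lambdoid",
    "sphenoidal_fontanelle",
    "mastoid_fontanelle",
)

SUTURE_PARTS: tuple[str, ...] = (
    "metopic",
    "sagittal",
    "coronal",
    "squamosal",
    "lambdoid",
)


class ValidationError(ValueError):
    """Raised when a domain invariant is violated."""


def _as_points(arr, name: str) -> np.ndarray:
    pts = np.asarray(arr, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValidationError(f"{name}: expected an (n, 3) array, got {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise ValidationError(f"corrupt input: non-finite coordinate in {name}")
    return pts


@dataclass
class BorderCurveSet:
    """Seven ordered 3D border polylines for one subject (mm)."""

    subject_id: str
    curves: list[np.ndarray]
    coordinate_frame: str = "LR-PA-IS"

    def __post_init__(self) -> None:
        if len(self.curves) != N_BORDERS:
            raise ValidationError(
                f"incomplete subject: expected {N_BORDERS} borders, got {len(self.curves)}"
            )
        validated = []
        for b, curve in enumerate(self.curves, start=1):
            pts = _as_points(curve, f"border {b}")
            if len(pts) < 2:
                raise ValidationError(f"degenerate border: border {b} has < 2 points")
            seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
            if np.any(seg == 0.0):
                raise ValidationError(
                    f"degenerate border: border {b} has consecutive identical points"
                )
            validated.append(pts)
        self.curves = validated

    def curve(self, border: int) -> np.ndarray:
        """Return the polyline for 1-based border index ``border``."""
        return self.curves[border - 1]

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "BorderCurveSet":
        return BorderCurveSet(
            self.subject_id,
            [c @ R.T + t for c in self.curves],
            self.coordinate_frame,
        )


@dataclass
class SemilandmarkSet:
    """Fixed-topology semilandmark representation of one subject.

    ``points`` concatenates the resampled borders in order; ``counts``
    records points per border.  Ordinals within each border are contiguous
    and strictly increasing by construction.
    """

    subject_id: str
    points: np.ndarray
    counts: tuple[int, ...] = DEFAULT_COUNTS

    def __post_init__(self) -> None:
        self.points = _as_points(self.points, "semilandmarks")
        self.counts = tuple(int(c) for c in self.counts)
        if len(self.counts) != N_BORDERS:
            raise ValidationError("counts must cover all 7 borders")
        if len(self.points) != sum(self.counts):
            raise ValidationError(
                f"point count {len(self.points)} != sum of per-border counts {sum(self.counts)}"
            )

    @property
    def offsets(self) -> np.ndarray:
        """Start index of each border in ``points`` (plus a final sentinel)."""
        return np.concatenate([[0], np.cumsum(self.counts)])

    def border_points(self, border: int) -> np.ndarray:
        off = self.offsets
        return self.points[off[border - 1]: off[border]]

    def global_index(self, border: int, ordinal: int) -> int:
        n = self.counts[border - 1]
        if not 0 <= ordinal < n:
            raise ValidationError(f"ordinal {ordinal} out of range for border {border}")
        return int(self.offsets[border - 1]) + ordinal

    def border_index(self) -> np.ndarray:
        """(n, 2) array of (border, ordinal) for every point, 1-based border."""
        rows = []
        for b, n in enumerate(self.counts, start=1):
            rows.append(np.column_stack([np.full(n, b), np.arange(n)]))
        return np.concatenate(rows).astype(int)

    def with_points(self, points: np.ndarray) -> "SemilandmarkSet":
        return SemilandmarkSet(self.subject_id, points, self.counts)

    def flat(self) -> np.ndarray:
        """Row vector of length 3 * n_points (x1, y1, z1, x2, ...)."""
        return self.points.reshape(-1)


@dataclass
class AnatomicalLandmarks:
    """Cranial landmarks for alignment and cranial measurements (mm).

    The alignment triplet is (rhinion, fmoR, fmoL); cranial measures use
    glabella, opisthocranion and the eurion pair.  ``axial_contour`` is
    an ordered closed polyline through glabella and opisthocranion used
    for the occipitofrontal circumference.
    """

    rhinion: np.ndarray
    fmoR: np.ndarray
    fmoL: np.ndarray
    glabella: np.ndarray
    opisthocranion: np.ndarray
    eurionL: np.ndarray
    eurionR: np.ndarray
    axial_contour: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("rhinion", "fmoR", "fmoL", "glabella",
                     "opisthocranion", "eurionL", "eurionR"):
            p = np.asarray(getattr(self, name), dtype=float).reshape(3)
            if not np.all(np.isfinite(p)):
                raise ValidationError(f"corrupt input: non-finite {name}")
            setattr(self, name, p)
        tri = np.stack([self.rhinion, self.fmoR, self.fmoL])
        area2 = np.linalg.norm(np.cross(tri[1] - tri[0], tri[2] - tri[0]))
        if area2 < 1e-9:
            raise ValidationError("alignment triplet is collinear")
        if self.axial_contour is not None:
            c = _as_points(self.axial_contour, "axial_contour")
            if len(c) < 3:
                raise ValidationError("axial contour needs >= 3 points")
            self.axial_contour = c

    @property
    def triplet(self) -> np.ndarray:
        return np.stack([self.rhinion, self.fmoR, self.fmoL])

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "AnatomicalLandmarks":
        def _tx(p):
            return None if p is None else np.asarray(p) @ R.T + t
        return AnatomicalLandmarks(
            *(getattr(self, n) @ R.T + t for n in
              ("rhinion", "fmoR", "fmoL", "glabella",
               "opisthocranion", "eurionL", "eurionR")),
            axial_contour=_tx(self.axial_contour),
        )


@dataclass
class WidthSeries:
    """Ordered per-semilandmark widths w_i (mm) between two borders."""

    values: np.ndarray
    source_borders: tuple[int, int]
    pairing_mode: str = "paired"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float).reshape(-1)
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValidationError("width series must be finite and >= 0")
        self.values = v
        if self.pairing_mode not in ("paired", "nearest"):
            raise ValidationError(f"unknown pairing mode {self.pairing_mode!r}")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class JunctionConfig:
    """Thresholds for junction-point detection.

    ``k_metopic`` / ``k_sagittal`` (mm) gate the width-jump criterion at
    the metopic->anterior-fontanelle and sagittal->posterior-fontanelle
    junctions; ``m_lateral`` (mm) thresholds the second-order width
    change for the 24 lateral junctions.  ``ratio_factor`` is the
    multiplier of the dominance clause (current increment must exceed
    ``ratio_factor * k`` times the previous increment).
    """

    k_metopic: float = 0.15
    k_sagittal: float = 0.18
    m_lateral: float = 0.4
    ratio_factor: float = 10.0
    #: algebraic reading of the detection criteria ("signed" | "absolute")
    strategy: str = "signed"
    #: the suture->fontanelle scan stops once the width first exceeds
    #: this multiple of the baseline suture width, so that later width
    #: jumps (fontanelle corners, lateral sutures) cannot refire the
    #: criterion; the flare onset itself always precedes the stop
    flare_stop_ratio: float = 1.4

    def __post_init__(self) -> None:
        if min(self.k_metopic, self.k_sagittal, self.m_lateral) <= 0:
            raise ValidationError("junction thresholds must be > 0")
        if self.strategy not in ("signed", "absolute"):
            raise ValidationError(f"unknown strategy {self.strategy!r}")


@dataclass
class JunctionPoint:
    label: str          # "JP1" .. "JP32"
    border: int         # 1-based border index
    ordinal: int        # 0-based ordinal within the border


@dataclass
class PartRange:
    """Half-open ordinal range [start, stop) on one border."""

    border: int
    start: int
    stop: int

    def __post_init__(self) -> None:
        if self.stop <= self.start:
            raise ValidationError(
                f"empty part range [{self.start}, {self.stop}) on border {self.border}"
            )

    def indices(self) -> np.ndarray:
        return np.arange(self.start, self.stop)


@dataclass
class SuturePartition:
    """32 junction points and the 9 named suture/fontanelle parts.

    Each part maps to the list of border index ranges that trace its
    boundary; suture parts carry their ranges in (side A..., side B...)
    order so sides can be paired for width/length measures.
    """

    junction_points: list[JunctionPoint]
    parts: dict[str, list[PartRange]]

    def __post_init__(self) -> None:
        if len(self.junction_points) != 32:
            raise ValidationError(
                f"expected 32 junction points, got {len(self.junction_points)}"
            )
        labels = [jp.label for jp in self.junction_points]
        if labels != [f"JP{i}" for i in range(1, 33)]:
            raise ValidationError("junction points must be labelled JP1..JP32 in order")
        missing = set(PART_NAMES) - set(self.parts)
        if missing or len(self.parts) != len(PART_NAMES):
            raise ValidationError(f"expected 9 named parts, missing {sorted(missing)}")

    def jp(self, number: int) -> JunctionPoint:
        return self.junction_points[number - 1]


@dataclass
class MorphometricRecord:
    """Per-subject cranial and suture measurements.

    L/W/C are cranial length/width/circumference (mm), S the total
    suture+fontanelle surface area (mm^2); per-suture length/width in mm
    and SI dimensionless (>= 1).  ``average_si`` is the unweighted mean
    of the five named sutures' SIs.
    """

    subject_id: str
    cranial_length: float
    cranial_width: float
    cranial_circumference: float | None
    suture_length: dict[str, float]
    suture_width: dict[str, float]
    suture_si: dict[str, float]
    total_surface_area: float
    average_si: float

    def __post_init__(self) -> None:
        for v, name in ((self.cranial_length, "L"), (self.cranial_width, "W"),
                        (self.total_surface_area, "S")):
            if not np.isfinite(v) or v < 0:
                raise ValidationError(f"{name} must be finite and >= 0")
        if self.cranial_circumference is not None:
            C = self.cranial_circumference
            if not np.isfinite(C) or C < 0:
                raise ValidationError("C must be finite and >= 0")
            if self.cranial_length > C or self.cranial_width > C:
                raise ValidationError("cranial chords L, W cannot exceed circumference C")
        for s in SUTURE_PARTS:
            if s not in self.suture_length or s not in self.suture_width or s not in self.suture_si:
                raise ValidationError(f"missing suture measurements for {s}")
            if self.suture_length[s] < 0 or self.suture_width[s] < 0:
                raise ValidationError(f"negative length/width for {s}")
            if self.suture_si[s] < 1.0 - 1e-9:
                raise ValidationError(f"sinuosity index < 1 for {s}")

    def covariates(self) -> dict[str, float]:
        return {
            "L": self.cranial_length,
            "W": self.cranial_width,
            "C": self.cranial_circumference,
            "S": self.total_surface_area,
            "SI": self.average_si,
        }


@dataclass
class TriangulatedSurface:
    """A lifted triangulated patch (mm)."""

    vertices: np.ndarray
    triangles: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = _as_points(self.vertices, "vertices")
        tri = np.asarray(self.triangles, dtype=int)
        if tri.ndim != 2 or tri.shape[1] != 3:
            raise ValidationError("triangles must be an (m, 3) index array")
        self.triangles = tri

    def side_lengths(self) -> np.ndarray:
        """(m, 3) side lengths a, b, c per triangle."""
        v = self.vertices[self.triangles]
        a = np.linalg.norm(v[:, 1] - v[:, 2], axis=1)
        b = np.linalg.norm(v[:, 0] - v[:, 2], axis=1)
        c = np.linalg.norm(v[:, 0] - v[:, 1], axis=1)
        return np.column_stack([a, b, c])

    def mean_edge_length(self) -> float:
        return float(self.side_lengths().mean())


@dataclass
class ShapeMatrix:
    """Raw and column-standardized geometry matrices.

    ``G0`` is N x 3p raw coordinates; ``G`` the z-scored matrix; the
    per-column mean/SD pair is the standardization operator Z
    (population SD; zero-variance columns pass through with SD treated
    as 1 and are flagged in ``constant_columns``).
    """

    G0: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    G: np.ndarray
    constant_columns: np.ndarray

    def inverse(self, G: np.ndarray) -> np.ndarray:
        return G * self.sd + self.mean


@dataclass
class ReducedModel:
    """A fitted dimension-reduction model with an inverse map.

    For classic PCA, ``basis`` holds the top-k eigenvector rows (k x 3p,
    orthonormal) and ``scores`` the N x k score matrix; non-linear
    methods store their fitted estimator in ``estimator`` and reconstruct
    through a learned pre-image map.
    """

    method: str
    k: int
    scores: np.ndarray
    explained_variance_ratio: np.ndarray | None = None
    basis: np.ndarray | None = None
    estimator: object | None = None

    def transform(self, G: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def inverse_transform(self, scores: np.ndarray) -> np.ndarray:
        raise NotImplementedError


@dataclass
class RegressionShapeModel:
    """PC-score regression model mapping covariates to geometry.

    ``coefficients`` is k x n_features; features are standardized with
    the stored mean/SD before multiplication, and an intercept column is
    appended when ``intercept`` is set.
    """

    feature_names: list[str]
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    intercept: bool
    coefficients: np.ndarray
    reduced: object           # ReducedModel (with inverse map)
    standardizer: ShapeMatrix
    training_range: np.ndarray | None = None   # (2, n_features) min/max raw

    def design_row(self, covariates: dict[str, float]) -> np.ndarray:
        raw = np.array([covariates[n] for n in self.feature_names], dtype=float)
        z = (raw - self.feature_mean) / self.feature_sd
        if self.intercept:
            z = np.concatenate([[1.0], z])
        return z
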