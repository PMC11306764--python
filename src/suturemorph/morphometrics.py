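"""Suture length, width, sinuosity index and cranial shape measures.

Suture parts are measured from their two border sides:

* length = mean of the two sides' polyline arc lengths (bilateral parts
  sum their left and right branches);
* width  = mean per-semilandmark gap, either paired (i-th point to i-th
  point; metopic and sagittal) or nearest (shortest distance from each
  point on one side to the opposite side);
* sinuosity index (SI) = arc length / endpoint chord per side, averaged
  over sides; 1 for a straight suture, > 1 with interdigitation.

Cranial shape parameters: length L = glabella-opisthocranion distance,
width W = eurion-eurion distance, circumference C = arc length of the
closed axial head contour through glabella and opisthocranion.
"""

from __future__ import annotations

import warnings

import numpy as np

from .borders import arc_length, compute_width_series, side_polyline
from .types import (
    AnatomicalLandmarks,
    MorphometricRecord,
    PartRange,
    SemilandmarkSet,
    SUTURE_PARTS,
    SuturePartition,
    ValidationError,
)

#: suture parts measured with the paired width rule
PAIRED_WIDTH_PARTS = ("metopic", "sagittal")


def _side_pairs(ranges: list[PartRange]) -> list[tuple[PartRange, PartRange]]:
    """Suture ranges are stored as consecutive (side A, side B) pairs."""
    if len(ranges) < 2 or len(ranges) % 2:
        raise ValidationError("suture part must have an even number of sides")
    return [(ranges[i], ranges[i + 1]) for i in range(0, len(ranges), 2)]


def suture_length(ranges: list[PartRange], sl: SemilandmarkSet) -> float:
    """Average length of both sides, summed over branches (mm)."""
    total = 0.0
    for a, b in _side_pairs(ranges):
        total += 0.5 * (arc_length(side_polyline(sl, a)) + arc_length(side_polyline(sl, b)))
    return total


def suture_width(
    ranges: list[PartRange],
    sl: SemilandmarkSet,
    mode: str = "nearest",
    part_name: str = "",
) -> float:
    """Mean gap between the two sides of a suture (mm)."""
    if mode == "paired" and part_name and part_name not in PAIRED_WIDTH_PARTS:
        warnings.warn(
            f"paired width is defined only for {PAIRED_WIDTH_PARTS}; "
            f"falling back to nearest for {part_name!r}"
        )
        mode = "nearest"
    widths = []
    for a, b in _side_pairs(ranges):
        A = side_polyline(sl, a)
        B = side_polyline(sl, b)
        widths.append(compute_width_series(A, B, mode=mode).values)
    return float(np.concatenate(widths).mean())


def sinuosity_index(ranges: list[PartRange], sl: SemilandmarkSet) -> float:
    """Arc length / endpoint chord per side, averaged over sides."""
    sis = []
    for pr in ranges:
        pts = side_polyline(sl, pr)
        chord = float(np.linalg.norm(pts[-1] - pts[0]))
        if chord <= 1e-12:
            raise ValidationError("closed curve has undefined SI")
        sis.append(arc_length(pts) / chord)
    return float(np.mean(sis))


def cranial_measurements(
    lm: AnatomicalLandmarks,
    contour_tolerance: float = 2.0,
) -> tuple[float, float, float | None]:
    """(L, W, C) in mm; C is ``None`` without an axial contour."""
    L = float(np.linalg.norm(lm.glabella - lm.opisthocranion))
    W = float(np.linalg.norm(lm.eurionL - lm.eurionR))
    C = None
    if lm.axial_contour is not None:
        contour = lm.axial_contour
        if np.linalg.norm(contour[0] - contour[-1]) > 1e-9:
            contour = np.vstack([contour, contour[0]])
        for name, p in (("glabella", lm.glabella), ("opisthocranion", lm.opisthocranion)):
            d = np.linalg.norm(contour - p, axis=1).min()
            if d > contour_tolerance:
                warnings.warn(
                    f"axial contour passes {d:.2f} mm from {name} "
                    f"(> {contour_tolerance} mm tolerance)"
                )
        C = arc_length(contour)
    return L, W, C


def measure_subject(
    sl: SemilandmarkSet,
    partition: SuturePartition,
    landmarks: AnatomicalLandmarks,
    total_surface_area: float,
) -> MorphometricRecord:
    """Assemble the full per-subject morphometric record."""
    L, W, C = cranial_measurements(landmarks)
    lengths, widths, sis = {}, {}, {}
    for name in SUTURE_PARTS:
        ranges = partition.parts[name]
        lengths[name] = suture_length(ranges, sl)
        mode = "paired" if name in PAIRED_WIDTH_PARTS else "nearest"
        widths[name] = suture_width(ranges, sl, mode=mode, part_name=name)
        sis[name] = max(1.0, sinuosity_index(ranges, sl))
    return MorphometricRecord(
        subject_id=sl.subject_id,
        cranial_length=L,
        cranial_width=W,
        cranial_circumference=C,
        suture_length=lengths,
        suture_width=widths,
        suture_si=sis,
        total_surface_area=total_surface_area,
        average_si=float(np.mean([sis[s] for s in SUTURE_PARTS])),
    )
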