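"""Border resampling and junction-point detection.

Traced border polylines are resampled to fixed per-border semilandmark
counts (default 100/100/200/200/50/50/100 = 800).  Thirty-two junction
points (JPs) then partition the borders into nine suture/fontanelle
parts:

* JP1/JP2 are the nasion starts of borders 1/2 and JP5/JP6 the
  parietal-corner starts of borders 3/4 (fixed by the topology);
* JP3/JP4 (metopic -> anterior fontanelle) and JP7/JP8 (sagittal ->
  posterior fontanelle) come from a first-order width-jump criterion on
  the paired width series of borders 1-2 and 3-4: index i qualifies when
  w[i+1] - w[i] > k and w[i+1] - w[i] > ratio_factor * k * (w[i] - w[i-1]),
  and the junction is the LAST qualifying index of the scan;
* JP9-JP32 (the 24 lateral junctions) come from a second-order width
  change criterion, (w[i+1] - w[i]) - (w[i] - w[i-1]) > m, evaluated on
  each border's nearest-distance series to the union of the other
  borders; each run of consecutive qualifying indices contributes its
  last index.

Because the width series of a suture kinks where the suture opens into
a fontanelle (flat gap -> widening flare) and again where a fontanelle
closes back into the next suture (narrowing flare -> flat gap), every
suture/fontanelle transition produces a positive second-difference
spike, so the lateral criterion recovers all remaining part boundaries.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .types import (
    DEFAULT_COUNTS,
    BorderCurveSet,
    JunctionConfig,
    JunctionPoint,
    PartRange,
    SemilandmarkSet,
    SuturePartition,
    ValidationError,
    WidthSeries,
)


class PartitionFailure(RuntimeError):
    """Raised when a required junction point cannot be identified."""


# ------------------------------------------------------------- resampling

def arc_length(points: np.ndarray) -> float:
    """Total chord-sum length of a polyline."""
    return float(np.linalg.norm(np.diff(points, axis=0), axis=1).sum())


def cumulative_arc_length(points: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def resample_border(curve: np.ndarray, n: int) -> np.ndarray:
    """Resample a polyline to ``n`` points at equal arc-length spacing.

    The first and last output points coincide with the curve endpoints
    and every output point lies on a segment of the input polyline.
    """
    curve = np.asarray(curve, dtype=float)
    if n < 2:
        raise ValueError("n must be >= 2")
    s = cumulative_arc_length(curve)
    total = s[-1]
    if total <= 0:
        raise ValidationError("degenerate border: zero arc length")
    targets = np.linspace(0.0, total, n)
    out = np.column_stack([np.interp(targets, s, curve[:, d]) for d in range(3)])
    out[0] = curve[0]
    out[-1] = curve[-1]
    return out


def assemble_semilandmarks(
    curves: BorderCurveSet,
    counts: tuple[int, ...] = DEFAULT_COUNTS,
) -> SemilandmarkSet:
    """Resample all seven borders and concatenate into one landmark set."""
    counts = tuple(int(c) for c in counts)
    if len(counts) != len(curves.curves):
        raise ValidationError(
            f"counts map has {len(counts)} entries for {len(curves.curves)} borders"
        )
    pts = np.concatenate(
        [resample_border(curves.curve(b), counts[b - 1])
         for b in range(1, len(counts) + 1)]
    )
    return SemilandmarkSet(curves.subject_id, pts, counts)


# ------------------------------------------------------------ width series

def compute_width_series(
    setA: np.ndarray,
    setB: np.ndarray,
    mode: str = "paired",
    source_borders: tuple[int, int] = (0, 0),
) -> WidthSeries:
    """Per-semilandmark widths between two borders.

    ``paired`` pairs the i-th points of each set; ``nearest`` takes, for
    each point of A, the distance to its nearest point on B.
    """
    A = np.asarray(setA, dtype=float)
    B = np.asarray(setB, dtype=float)
    if mode == "paired":
        if len(A) != len(B):
            raise ValidationError(
                f"paired mode requires equal counts ({len(A)} vs {len(B)})"
            )
        w = np.linalg.norm(A - B, axis=1)
    elif mode == "nearest":
        w, _ = cKDTree(B).query(A)
    else:
        raise ValueError(f"unknown pairing mode {mode!r}")
    return WidthSeries(w, source_borders, mode)


# -------------------------------------------------------- junction criteria

def _diffs(w: np.ndarray, strategy: str) -> tuple[np.ndarray, np.ndarray]:
    """First increments at i (current = w[i+1]-w[i], previous = w[i]-w[i-1])."""
    cur = w[2:] - w[1:-1]
    prev = w[1:-1] - w[:-2]
    if strategy == "absolute":
        cur, prev = np.abs(cur), np.abs(prev)
    return cur, prev


def find_fontanelle_junction(
    widths: WidthSeries | np.ndarray,
    k: float,
    start: int = 1,
    ratio_factor: float = 10.0,
    strategy: str = "signed",
) -> int | None:
    """Last index where the width jump exceeds k and dominates the
    previous increment; ``None`` when no index qualifies."""
    w = widths.values if isinstance(widths, WidthSeries) else np.asarray(widths, float)
    if len(w) < 3:
        raise ValidationError("width series must have >= 3 values")
    if not 1 <= start <= len(w) - 2:
        raise ValueError(f"start {start} out of range [1, {len(w) - 2}]")
    cur, prev = _diffs(w, strategy)          # index i corresponds to w-index i+1
    i = np.arange(1, len(w) - 1)
    hits = (cur > k) & (cur > ratio_factor * k * prev) & (i >= start)
    idx = i[hits]
    return int(idx[-1]) if len(idx) else None


def _second_differences(w: np.ndarray, strategy: str) -> np.ndarray:
    if strategy == "absolute":
        return np.abs(w[2:] - 2 * w[1:-1] + w[:-2])
    return w[2:] - 2 * w[1:-1] + w[:-2]


def find_lateral_junctions(
    widths: WidthSeries | np.ndarray,
    m: float,
    start: int = 1,
    stop: int | None = None,
    strategy: str = "signed",
    with_values: bool = False,
):
    """Indices where the second-order width change exceeds ``m``.

    Consecutive qualifying indices collapse to the last index of their
    run (the same "final set of points" rule as the fontanelle
    criterion).  ``with_values`` additionally returns each run's peak
    second difference.
    """
    w = widths.values if isinstance(widths, WidthSeries) else np.asarray(widths, float)
    if len(w) < 3:
        raise ValidationError("width series must have >= 3 values")
    d2 = _second_differences(w, strategy)     # entry j corresponds to w-index j+1
    i = np.arange(1, len(w) - 1)
    mask = d2 > m
    mask &= i >= start
    if stop is not None:
        mask &= i < stop
    hits = i[mask]
    vals = d2[mask]
    out_idx: list[int] = []
    out_val: list[float] = []
    for j, v in zip(hits, vals):
        if out_idx and j == out_idx[-1] + 1:
            out_idx[-1] = int(j)
            out_val[-1] = max(out_val[-1], float(v))
        else:
            out_idx.append(int(j))
            out_val.append(float(v))
    if with_values:
        return out_idx, out_val
    return out_idx


# ------------------------------------------------------------- partitioning

def _union_width_series(sl: SemilandmarkSet, border: int) -> WidthSeries:
    """Nearest-distance series from one border to all other borders."""
    A = sl.border_points(border)
    others = np.concatenate(
        [sl.border_points(b) for b in range(1, len(sl.counts) + 1) if b != border]
    )
    return compute_width_series(A, others, mode="nearest",
                                source_borders=(border, 0))


#: lateral-junction layout: border -> (n expected, JP labels in scan order)
_LATERAL_LAYOUT: dict[int, list[int]] = {
    1: [9, 10],
    2: [11, 12],
    3: [13, 14, 15, 16, 17, 18],
    4: [19, 20, 21, 22, 23, 24],
    5: [25, 26],
    6: [27, 28],
    7: [29, 30, 31, 32],
}


def partition_sutures(
    sl: SemilandmarkSet,
    cfg: JunctionConfig | None = None,
) -> SuturePartition:
    """Identify all 32 junction points and assemble the 9 named parts.

    Part ranges are half-open ``[start, stop)`` in 0-based border
    ordinals, disjoint within each border and bounded by junction
    points; the final part on a border runs to the border's end.
    """
    cfg = cfg or JunctionConfig()
    n = dict(enumerate(sl.counts, start=1))

    def flare_scan(w: np.ndarray) -> np.ndarray:
        """Truncate a paired width series where the fontanelle flare has
        clearly begun, so later jumps cannot out-vote the onset."""
        base = np.median(w[:max(8, len(w) // 4)])
        over = np.where(w > cfg.flare_stop_ratio * base)[0]
        return w if len(over) == 0 else w[: over[0] + 2]

    w12 = compute_width_series(sl.border_points(1), sl.border_points(2),
                               "paired", (1, 2))
    jp3 = find_fontanelle_junction(flare_scan(w12.values), cfg.k_metopic,
                                   ratio_factor=cfg.ratio_factor,
                                   strategy=cfg.strategy)
    if jp3 is None:
        raise PartitionFailure("partition failure: JP3 (metopic/anterior-fontanelle)")

    w34 = compute_width_series(sl.border_points(3), sl.border_points(4),
                               "paired", (3, 4))
    jp7 = find_fontanelle_junction(flare_scan(w34.values), cfg.k_sagittal,
                                   ratio_factor=cfg.ratio_factor,
                                   strategy=cfg.strategy)
    if jp7 is None:
        raise PartitionFailure("partition failure: JP7 (sagittal/posterior-fontanelle)")

    ordinals: dict[int, int] = {1: 0, 2: 0, 3: jp3, 4: jp3, 5: 0, 6: 0, 7: jp7, 8: jp7}

    lateral_start = {1: jp3 + 2, 2: jp3 + 2, 3: jp7 + 2, 4: jp7 + 2,
                     5: 1, 6: 1, 7: 1}
    for border, labels in _LATERAL_LAYOUT.items():
        series = _union_width_series(sl, border)
        idx, vals = find_lateral_junctions(
            series, cfg.m_lateral, start=lateral_start[border],
            strategy=cfg.strategy, with_values=True,
        )
        want = len(labels)
        if len(idx) < want:
            missing = labels[len(idx)]
            raise PartitionFailure(
                f"partition failure: JP{missing} (border {border}: found "
                f"{len(idx)} of {want} lateral junctions)"
            )
        if len(idx) > want:
            # keep the strongest spikes, restore scan order
            keep = sorted(np.argsort(vals)[-want:])
            idx = [idx[j] for j in keep]
        for label, ordinal in zip(labels, idx):
            ordinals[label] = ordinal

    jp_border = {1: 1, 2: 2, 3: 1, 4: 2, 5: 3, 6: 4, 7: 3, 8: 4,
                 9: 1, 10: 1, 11: 2, 12: 2,
                 13: 3, 14: 3, 15: 3, 16: 3, 17: 3, 18: 3,
                 19: 4, 20: 4, 21: 4, 22: 4, 23: 4, 24: 4,
                 25: 5, 26: 5, 27: 6, 28: 6,
                 29: 7, 30: 7, 31: 7, 32: 7}
    jps = [JunctionPoint(f"JP{i}", jp_border[i], ordinals[i]) for i in range(1, 33)]

    o = ordinals
    parts = {
        "metopic": [PartRange(1, 0, o[3]), PartRange(2, 0, o[4])],
        "anterior_fontanelle": [
            PartRange(1, o[3], o[9]), PartRange(2, o[4], o[11]),
            PartRange(3, o[18], n[3]), PartRange(4, o[24], n[4]),
        ],
        "sagittal": [PartRange(3, 0, o[7]), PartRange(4, 0, o[8])],
        "posterior_fontanelle": [
            PartRange(3, o[7], o[13]), PartRange(4, o[8], o[19]),
            PartRange(7, o[30], o[31]),
        ],
        "coronal": [
            PartRange(1, o[9], o[10]), PartRange(3, o[17], o[18]),
            PartRange(2, o[11], o[12]), PartRange(4, o[23], o[24]),
        ],
        "squamosal": [
            PartRange(3, o[15], o[16]), PartRange(5, o[25], o[26]),
            PartRange(4, o[21], o[22]), PartRange(6, o[27], o[28]),
        ],
        "lambdoid": [
            PartRange(3, o[13], o[14]), PartRange(7, o[29], o[30]),
            PartRange(4, o[19], o[20]), PartRange(7, o[31], o[32]),
        ],
        "sphenoidal_fontanelle": [
            PartRange(1, o[10], n[1]), PartRange(3, o[16], o[17]),
            PartRange(5, 0, o[25]),
            PartRange(2, o[12], n[2]), PartRange(4, o[22], o[23]),
            PartRange(6, 0, o[27]),
        ],
        "mastoid_fontanelle": [
            PartRange(3, o[14], o[15]), PartRange(5, o[26], n[5]),
            PartRange(7, 0, o[29]),
            PartRange(4, o[20], o[21]), PartRange(6, o[28], n[6]),
            PartRange(7, o[32], n[7]),
        ],
    }
    return SuturePartition(jps, parts)


def side_polyline(sl: SemilandmarkSet, pr: PartRange) -> np.ndarray:
    """Extract a part-range polyline including its closing junction point.

    Ranges are stored half-open so adjacent parts stay disjoint; for arc
    length and chord measures the shared boundary point belongs to both
    sides, so the point at ``stop`` is appended when it exists.
    """
    pts = sl.border_points(pr.border)
    stop = min(pr.stop + 1, len(pts))
    return pts[pr.start: stop]
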