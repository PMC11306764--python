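"""Rigid alignment, form-space GPA and sliding semilandmarks.

* Three-point rigid alignment: least-squares rotation + translation
  (no scaling, det(R) = +1) between the (rhinion, fmoR, fmoL) triplets,
  applied to all subject geometry.
* Generalized Procrustes Analysis in *form space*: translation to a
  common centroid and rotation to an evolving consensus, with no
  scaling step, so every subject keeps its original centroid size.
* Sliding semilandmarks: each non-anchor point may move along its local
  curve tangent; the step minimizes the thin-plate-spline bending
  energy of the subject against the current consensus (one spline per
  coordinate axis), after which points are re-projected onto their
  source border polyline.  The 3D TPS kernel U(r) = -r is used for the
  bending-energy matrix.  A backtracking step guarantees the energy
  never increases after re-projection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .types import AnatomicalLandmarks, SemilandmarkSet, ValidationError


# ------------------------------------------------------------ rigid Kabsch

def kabsch(moving: np.ndarray, fixed: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares proper rigid transform: fixed ~ moving @ R.T + t."""
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    cm = moving.mean(axis=0)
    cf = fixed.mean(axis=0)
    H = (moving - cm).T @ (fixed - cf)
    U, sv, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    if d < 0 and sv[-1] > 1e-9 * max(sv[0], 1e-30):
        # genuinely reflection-optimal (not just a rank-deficient system)
        warnings.warn("reflection-optimal correspondence; using proper rotation")
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cf - R @ cm
    return R, t


def rigid_align_three_points(
    moving: AnatomicalLandmarks,
    fixed: AnatomicalLandmarks,
) -> tuple[np.ndarray, np.ndarray]:
    """Transform (R, t) aligning the moving (rhinion, fmoR, fmoL) triplet
    to the fixed one; apply to geometry as ``x @ R.T + t``."""
    return kabsch(moving.triplet, fixed.triplet)


def transform_points(points: np.ndarray, R: np.ndarray, t: np.ndarray) -> np.ndarray:
    return np.asarray(points) @ R.T + t


def transform_matrix(R: np.ndarray, t: np.ndarray) -> np.ndarray:
    """4x4 homogeneous form, for serialization."""
    M = np.eye(4)
    M[:3, :3] = R
    M[:3, 3] = t
    return M


# ---------------------------------------------------------------- GPA

def centroid_size(points: np.ndarray) -> float:
    c = points.mean(axis=0)
    return float(np.sqrt(((points - c) ** 2).sum()))


@dataclass
class GPAResult:
    aligned: list[SemilandmarkSet]
    consensus: np.ndarray
    transforms: list[tuple[np.ndarray, np.ndarray]]   # (R, t) per subject
    iterations: int
    objective_trace: list[float]


def gpa_form_space(
    shapes: list[SemilandmarkSet],
    max_iter: int = 100,
    tol: float = 1e-10,
) -> GPAResult:
    """Iterative Procrustes superimposition without scaling.

    Centroid size of every output equals its input (rigid motions
    only).  Convergence when the consensus moves less than ``tol``
    (RMS) between iterations.
    """
    if len(shapes) < 2:
        raise ValidationError("GPA needs >= 2 shapes")
    counts = shapes[0].counts
    if any(s.counts != counts for s in shapes):
        raise ValidationError("topology mismatch across shapes")

    X = [s.points - s.points.mean(axis=0) for s in shapes]
    R_acc = [np.eye(3) for _ in shapes]
    t_acc = [-s.points.mean(axis=0) for s in shapes]

    consensus = X[0].copy()
    trace: list[float] = []
    it = 0
    for it in range(1, max_iter + 1):
        for i, xi in enumerate(X):
            R, _ = kabsch(xi, consensus)
            X[i] = xi @ R.T
            R_acc[i] = R @ R_acc[i]
            t_acc[i] = R @ t_acc[i]
        new_consensus = np.mean(X, axis=0)
        trace.append(float(sum(((xi - new_consensus) ** 2).sum() for xi in X)))
        delta = np.sqrt(((new_consensus - consensus) ** 2).mean())
        consensus = new_consensus
        if delta < tol:
            break
    aligned = [s.with_points(x) for s, x in zip(shapes, X)]
    return GPAResult(aligned, consensus, list(zip(R_acc, t_acc)), it, trace)


# -------------------------------------------------------- bending energy

def bending_energy_matrix(Q: np.ndarray, ridge: float = 0.0) -> np.ndarray:
    """Bending-energy matrix L_k^-1 of the TPS anchored at Q (n x 3).

    Built from the 3D kernel U(r) = -r with an affine tail; the result
    is the top-left n x n block of the inverse of [[K P], [P' 0]].
    """
    Q = np.asarray(Q, dtype=float)
    n = len(Q)
    d = np.linalg.norm(Q[:, None, :] - Q[None, :, :], axis=2)
    K = -d
    if ridge:
        K = K + ridge * np.eye(n)
    P = np.column_stack([np.ones(n), Q])
    L = np.zeros((n + 4, n + 4))
    L[:n, :n] = K
    L[:n, n:] = P
    L[n:, :n] = P.T
    try:
        Linv = np.linalg.inv(L)
    except np.linalg.LinAlgError:
        warnings.warn("singular bending-energy system; ridge-stabilized solve")
        Linv = np.linalg.inv(L + 1e-8 * np.eye(n + 4))
    Be = Linv[:n, :n]
    return 0.5 * (Be + Be.T)


def bending_energy(X: np.ndarray, Be: np.ndarray) -> float:
    """Sum over the coordinate-axis splines of x' Be x."""
    return float(np.einsum("id,ij,jd->", X, Be, X))


# ------------------------------------------------------------- sliding

def _curve_tangents(points: np.ndarray, counts: tuple[int, ...]) -> np.ndarray:
    """Unit tangents from curve-neighbour central differences, per border."""
    tangents = np.zeros_like(points)
    start = 0
    for c in counts:
        seg = points[start: start + c]
        t = np.empty_like(seg)
        t[1:-1] = seg[2:] - seg[:-2]
        t[0] = seg[1] - seg[0]
        t[-1] = seg[-1] - seg[-2]
        norm = np.linalg.norm(t, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        tangents[start: start + c] = t / norm
        start += c
    return tangents


def _project_to_polyline(points: np.ndarray, polyline: np.ndarray) -> np.ndarray:
    """Closest point on a polyline for each query point."""
    A = polyline[:-1]
    AB = polyline[1:] - A
    denom = (AB ** 2).sum(axis=1)
    denom[denom == 0] = 1.0
    out = np.empty_like(points)
    for i, p in enumerate(points):
        t = np.clip(((p - A) * AB).sum(axis=1) / denom, 0.0, 1.0)
        cand = A + t[:, None] * AB
        j = np.argmin(((cand - p) ** 2).sum(axis=1))
        out[i] = cand[j]
    return out


@dataclass
class SlideResult:
    shapes: list[SemilandmarkSet]
    consensus: np.ndarray
    #: (iterations, n_shapes, 2): bending energy before/after each
    #: iteration's relaxation, both under that iteration's consensus
    energy_history: np.ndarray


def slide_semilandmarks(
    shapes: list[SemilandmarkSet],
    anchors: np.ndarray,
    iterations: int = 3,
    source_curves: list[list[np.ndarray]] | None = None,
    max_backtrack: int = 8,
    realign: bool = True,
) -> SlideResult:
    """Relax semilandmarks along their curves against the consensus.

    ``anchors`` are global point indices (junctions and border
    endpoints) that never move.  ``source_curves`` optionally provides,
    per subject, the seven original border polylines to re-project onto
    (in the same frame as ``shapes``); by default each subject's initial
    semilandmark polylines serve as the source geometry.  With
    ``realign=False`` the shapes are taken as already superimposed and no
    GPA is interleaved, so anchors stay exactly fixed.  GPA is re-run
    between iterations; bending energy versus the consensus is
    non-increasing for every shape at every iteration (a backtracking
    line search absorbs the re-projection error).
    """
    shapes = [s.with_points(s.points.copy()) for s in shapes]
    counts = shapes[0].counts
    n = sum(counts)
    anchors = np.asarray(anchors, dtype=int)
    slide_idx = np.setdiff1d(np.arange(n), anchors)

    # per-subject source polylines, carried through every realignment
    if source_curves is None:
        polylines = [
            [s.border_points(b).copy() for b in range(1, len(counts) + 1)]
            for s in shapes
        ]
    else:
        polylines = [[np.asarray(c, dtype=float).copy() for c in subj]
                     for subj in source_curves]

    border_of = shapes[0].border_index()[:, 0]

    if realign:
        gpa = gpa_form_space(shapes)
        shapes = gpa.aligned
        for subj, (R, t) in zip(polylines, gpa.transforms):
            for j, c in enumerate(subj):
                subj[j] = c @ R.T + t
        consensus = gpa.consensus
    else:
        consensus = np.mean([s.points for s in shapes], axis=0)

    history = np.zeros((iterations, len(shapes), 2))

    for it in range(iterations):
        Be = bending_energy_matrix(consensus)
        for si, shape in enumerate(shapes):
            X = shape.points
            E0 = bending_energy(X - consensus, Be)
            history[it, si, 0] = E0
            T = _curve_tangents(X, counts)[slide_idx]

            Bss = Be[np.ix_(slide_idx, slide_idx)]
            A = Bss * (T @ T.T)
            BX = Be @ (X - consensus)
            b = np.einsum("ad,ad->a", T, BX[slide_idx])
            try:
                theta = np.linalg.solve(A + 1e-10 * np.eye(len(A)), -b)
            except np.linalg.LinAlgError:
                warnings.warn("singular sliding system; ridge-stabilized solve")
                theta = np.linalg.solve(A + 1e-6 * np.eye(len(A)), -b)

            best = X
            best_E = E0
            scale = 1.0
            for _ in range(max_backtrack):
                Xc = X.copy()
                Xc[slide_idx] = Xc[slide_idx] + scale * theta[:, None] * T
                # hard re-projection onto the source polylines
                for b_i in range(1, len(counts) + 1):
                    sel = np.where(border_of == b_i)[0]
                    sel = np.intersect1d(sel, slide_idx)
                    if len(sel):
                        Xc[sel] = _project_to_polyline(Xc[sel], polylines[si][b_i - 1])
                E = bending_energy(Xc - consensus, Be)
                if E <= best_E + 1e-12 * max(1.0, abs(best_E)):
                    best, best_E = Xc, E
                    break
                scale *= 0.5
            shapes[si] = shape.with_points(best)
            history[it, si, 1] = best_E

        if realign:
            gpa = gpa_form_space(shapes)
            shapes = gpa.aligned
            for subj, (R, t) in zip(polylines, gpa.transforms):
                for j, c in enumerate(subj):
                    subj[j] = c @ R.T + t
            consensus = gpa.consensus
        else:
            consensus = np.mean([s.points for s in shapes], axis=0)

    return SlideResult(shapes, consensus, history)


def default_anchors(sl: SemilandmarkSet, partition=None) -> np.ndarray:
    """Border endpoints plus, when a partition is given, all junction points."""
    idx = []
    off = sl.offsets
    for b in range(len(sl.counts)):
        idx += [int(off[b]), int(off[b + 1] - 1)]
    if partition is not None:
        for jp in partition.junction_points:
            idx.append(sl.global_index(jp.border, jp.ordinal))
    return np.unique(idx)
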