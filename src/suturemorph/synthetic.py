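"""Synthetic infant-cranium border-curve populations with ground truth.

The generator lays the seven-border suture/fontanelle topology onto a
half-ellipsoid cranial vault (half-axes a_x, a_y, a_z; X = left->right,
Y = posterior->anterior, Z = inferior->superior):

* a midline chain nasion -> metopic suture -> rhombic anterior
  fontanelle -> sagittal suture -> rhombic posterior fontanelle;
* bilateral coronal, squamosal and lambdoid sutures joining the
  sphenoidal (pterion) and mastoid (asterion) fontanelles, modelled as
  small openings with free-edge stubs;
* suture sides offset from a centerline by half the suture width, with
  an in-phase sinusoidal interdigitation (both sides wave together, so
  the gap width stays constant while the sinuosity index rises).

Per-subject variation is *exactly linear* in three latent factors --
overall size, fontanelle area, and interdigitation amplitude -- via
displacement fields obtained by differencing perturbed templates:

    X(u) = X0 + u1 * c_size * X0 + u2 * (X_area - X0) + u3 * (X_si - X0)

plus optional smooth (correlated) tracing noise added only after all
ground truth is measured.  Ground truth records the junction ordinals
of all 32 junction points, dense-quadrature suture lengths/widths/SIs,
and the cranial L/W/C.

Default base values emulate a 2-4 month infant population: cranial
length 125.44 mm, width 107.03 mm, circumference ~367 mm, suture widths
1.54/5.45/1.88/2.24/2.62 mm (metopic/sagittal/coronal/squamosal/
lambdoid), ~6 % size variation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .borders import arc_length, cumulative_arc_length, resample_border
from .types import (
    DEFAULT_COUNTS,
    AnatomicalLandmarks,
    BorderCurveSet,
    SemilandmarkSet,
    ValidationError,
)

SUTURE_ORDER = ("metopic", "sagittal", "coronal", "squamosal", "lambdoid")


@dataclass
class SyntheticConfig:
    """Population parameters; ``seed`` is mandatory."""

    seed: int
    n_subjects: int = 69
    half_axes: tuple[float, float, float] = (53.515, 62.72, 65.0)
    size_cv: float = 0.06                 # proportional scale per sigma of u_size
    metopic_length: float = 52.0
    sagittal_length: float = 91.0
    coronal_length: float = 65.0
    squamosal_length: float = 58.0
    af_diagonals: tuple[float, float] = (30.0, 25.0)   # (AP, ML), mm
    pf_diagonals: tuple[float, float] = (16.0, 14.0)
    area_effect: float = 0.07             # relative diagonal growth per sigma
    suture_widths: dict = field(default_factory=lambda: {
        "metopic": 1.54, "sagittal": 5.45, "coronal": 1.88,
        "squamosal": 2.24, "lambdoid": 2.62,
    })
    #: suture -> (amplitude mm, wavelength mm, phase rad)
    interdigitation: dict = field(default_factory=lambda: {
        "metopic": (0.35, 12.0, 0.0), "sagittal": (1.2, 14.0, 1.3),
        "coronal": (0.45, 14.0, 0.7), "squamosal": (0.4, 14.0, 2.1),
        "lambdoid": (0.5, 15.0, 0.4),
    })
    si_effect: float = 0.3                # relative amplitude growth per sigma
    #: (length mm, per-side extra mm): linear opening of the lambdoid
    #: into the posterior fontanelle; the junction is the flare onset
    pf_flare: tuple[float, float] = (6.0, 4.0)
    latent_clip: float = 2.5              # truncate latent draws (anatomical plausibility)
    sphenoidal_radius: float = 7.0
    mastoid_radius: float = 6.0
    noise_sd: float = 0.1                 # mm, smooth tracing error
    noise_corr_length: float = 10.0       # mm along the border
    density: float = 3.0                  # dense construction points per mm
    counts: tuple[int, ...] = DEFAULT_COUNTS

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("seed is mandatory")
        ax, ay, az = self.half_axes
        if min(ax, ay, az) <= 0 or self.density <= 0:
            raise ValidationError("length scales must be > 0")
        if self.af_diagonals[1] >= ax or self.pf_diagonals[1] >= ax:
            raise ValidationError(
                "geometrically inconsistent config: fontanelle wider than vault"
            )
        for w in self.suture_widths.values():
            if w < 0:
                raise ValidationError("suture widths must be >= 0")


@dataclass
class GroundTruth:
    """Analytic/dense-quadrature truth recorded before noise is added."""

    junction_ordinals: dict[str, tuple[int, int]]   # JP label -> (border, ordinal)
    suture_length: dict[str, float]
    suture_width: dict[str, float]
    suture_si: dict[str, float]
    cranial_length: float
    cranial_width: float
    cranial_circumference: float
    approx_footprint_area: float
    latents: np.ndarray


@dataclass
class SyntheticSubject:
    curves: BorderCurveSet
    landmarks: AnatomicalLandmarks
    truth: GroundTruth
    #: exact-linear semilandmark representation (see _Model.semilandmarks)
    semilandmarks: SemilandmarkSet | None = None


@dataclass
class SyntheticPopulation:
    config: SyntheticConfig
    subjects: list[SyntheticSubject]
    latents: np.ndarray                   # (n, 3): size, area, sinuosity

    def __len__(self) -> int:
        return len(self.subjects)

    def semilandmark_sets(self) -> list[SemilandmarkSet]:
        return [s.semilandmarks for s in self.subjects]

    def semilandmark_matrix(self) -> np.ndarray:
        """N x 3p raw geometry matrix from the exact-linear product."""
        return np.stack([s.semilandmarks.flat() for s in self.subjects])


# ----------------------------------------------------- ellipsoid geometry

def _surf(t, psi, axes):
    ax, ay, az = axes
    t = np.asarray(t, dtype=float)
    psi = np.asarray(psi, dtype=float)
    return np.stack([ax * np.sin(t) * np.sin(psi),
                     ay * np.cos(t) * np.ones_like(psi),
                     az * np.sin(t) * np.cos(psi)], axis=-1)


def _metrics(t, psi, axes):
    ax, ay, az = axes
    gt = np.sqrt((ax * np.cos(t) * np.sin(psi)) ** 2
                 + (ay * np.sin(t)) ** 2
                 + (az * np.cos(t) * np.cos(psi)) ** 2)
    gp = np.sqrt((ax * np.sin(t) * np.cos(psi)) ** 2
                 + (az * np.sin(t) * np.sin(psi)) ** 2)
    return gt, gp


def _project(pts, axes):
    ax, ay, az = axes
    q = np.sqrt((pts[..., 0] / ax) ** 2 + (pts[..., 1] / ay) ** 2
                + (pts[..., 2] / az) ** 2)
    return pts / q[..., None]


def _mirror(pts):
    return np.asarray(pts) * np.array([-1.0, 1.0, 1.0])


class _Vault:
    """Meridian arc-length table and parameter-space helpers."""

    def __init__(self, axes):
        self.axes = axes
        ts = np.linspace(0.0, np.pi, 4096)
        pts = _surf(ts, np.zeros_like(ts), axes)
        self.ts = ts
        self.s_of_t = cumulative_arc_length(pts)
        self.total = float(self.s_of_t[-1])

    def t_at(self, s: float) -> float:
        return float(np.interp(s, self.s_of_t, self.ts))

    def offset(self, p, mm_t: float, mm_psi: float):
        """Displace a (t, psi) parameter point by local millimetres."""
        gt, gp = _metrics(p[0], p[1], self.axes)
        return (p[0] + mm_t / max(gt, 1e-9), p[1] + mm_psi / max(gp, 1e-9))

    def seg(self, p0, p1, n: int) -> np.ndarray:
        """Dense 3D polyline along a straight parameter-space path."""
        t = np.linspace(p0[0], p1[0], n)
        psi = np.linspace(p0[1], p1[1], n)
        return _surf(t, psi, self.axes)

    def seg_len(self, p0, p1, n: int = 257) -> float:
        return arc_length(self.seg(p0, p1, n))

    def bezier(self, a, ctrl, b, n: int) -> np.ndarray:
        """Quadratic surface Bezier with an explicit control point."""
        a = np.asarray(a, float)
        b = np.asarray(b, float)
        ctrl = np.asarray(ctrl, float)
        s = np.linspace(0.0, 1.0, n)[:, None]
        pts = (1 - s) ** 2 * a + 2 * s * (1 - s) * ctrl + s ** 2 * b
        return _project(pts, self.axes)

    def chord(self, a, b, n: int, bow: np.ndarray | None = None) -> np.ndarray:
        """Dense surface chord between two 3D points; an optional ``bow``
        displacement (mm) curves it through a quadratic Bezier midpoint."""
        a = np.asarray(a, float)
        b = np.asarray(b, float)
        if bow is None:
            pts = np.linspace(a, b, n)
        else:
            ctrl = 0.5 * (a + b) + np.asarray(bow, float)
            s = np.linspace(0.0, 1.0, n)[:, None]
            pts = (1 - s) ** 2 * a + 2 * s * (1 - s) * ctrl + s ** 2 * b
        return _project(pts, self.axes)


def _side(center: np.ndarray, sign: float, width: float,
          amp: float, wavelength: float, phase: float,
          ref: np.ndarray, axes,
          start_flare: tuple[float, float] | None = None,
          end_flare: tuple[float, float] | None = None) -> np.ndarray:
    """Offset a suture centerline to one side, with an in-phase wave.

    ``start_flare``/``end_flare = (length_mm, extra_mm)`` widen the
    half-offset linearly from +extra at the respective centerline end
    down to 0 at ``length_mm`` inside -- the suture flaring open into a
    fontanelle.
    """
    T = np.empty_like(center)
    T[1:-1] = center[2:] - center[:-2]
    T[0] = center[1] - center[0]
    T[-1] = center[-1] - center[-2]
    ax, ay, az = axes
    N = center / np.array([ax ** 2, ay ** 2, az ** 2])
    D = np.cross(T, N)
    D /= np.linalg.norm(D, axis=1, keepdims=True)
    flip = np.sign(D @ np.asarray(ref, float))
    flip[flip == 0] = 1.0
    D *= flip[:, None]
    s = cumulative_arc_length(center)
    # taper the wave to zero at both suture ends so that junction
    # endpoints stay at the clean +-w/2 offsets (and left/right borders
    # keep exactly mirrored arc lengths)
    ramp = min(wavelength, s[-1] / 3.0)
    env = np.clip(s / ramp, 0.0, 1.0) * np.clip((s[-1] - s) / ramp, 0.0, 1.0)
    env = env * env * (3.0 - 2.0 * env)      # smoothstep shoulders
    half = np.full_like(s, width / 2.0)
    if start_flare is not None:
        f_len, f_extra = start_flare
        half = half + f_extra * np.clip(1.0 - s / f_len, 0.0, 1.0)
    if end_flare is not None:
        f_len, f_extra = end_flare
        half = half + f_extra * np.clip(1.0 - (s[-1] - s) / f_len, 0.0, 1.0)
    disp = sign * half + env * amp * np.sin(
        2 * np.pi * s / wavelength + phase)
    return _project(center + disp[:, None] * D, axes)


def _port(vault, center, radius, theta_deg):
    """Point on a fontanelle rim: local frame 0 deg = posterior (+t),
    90 deg = lateral-inferior (+psi)."""
    th = np.deg2rad(theta_deg)
    return vault.offset(center, radius * np.cos(th), radius * np.sin(th))


def _local_angle(vault, center, target) -> float:
    """Angle of the direction center -> target in the local mm frame."""
    gt, gp = _metrics(center[0], center[1], vault.axes)
    d_t = (target[0] - center[0]) * gt
    d_p = (target[1] - center[1]) * gp
    return float(np.arctan2(d_p, d_t))


def _free_ports(vault, center, radius, a_first, a_second, spread=0.75):
    """Two free-edge rim points on the arc facing away from the two
    suture directions (angles ``a_first``/``a_second``), each rotated
    ``spread`` radians from the free-arc centre toward its suture."""
    v = -(np.array([np.cos(a_first), np.sin(a_first)])
          + np.array([np.cos(a_second), np.sin(a_second)]))
    a_free = float(np.arctan2(v[1], v[0]))

    def towards(a_s):
        d = (a_s - a_free + np.pi) % (2 * np.pi) - np.pi
        return np.sign(d) if d != 0 else 1.0

    p1 = _port(vault, center, radius, np.rad2deg(a_free + spread * towards(a_first)))
    p2 = _port(vault, center, radius, np.rad2deg(a_free + spread * towards(a_second)))
    return p1, p2


# -------------------------------------------------------- template build

@dataclass
class _Segment:
    name: str
    pts: np.ndarray        # includes both endpoints


class _Template:
    """Dense 7-border layout with named segments and side registry."""

    def __init__(self):
        self.borders: list[np.ndarray] = []
        self.seg_names: list[list[tuple[str, int]]] = []  # (name, end dense idx)
        self.sides: dict[str, np.ndarray] = {}
        self.landmarks: dict[str, np.ndarray] = {}
        self.contour: np.ndarray | None = None

    def all_points(self) -> np.ndarray:
        return np.concatenate(self.borders)

    def split(self, flat: np.ndarray) -> list[np.ndarray]:
        out = []
        start = 0
        for b in self.borders:
            out.append(flat[start: start + len(b)])
            start += len(b)
        return out


def _append_border(template: _Template, segments: list[_Segment]) -> None:
    pts = [segments[0].pts]
    names = [(segments[0].name, len(segments[0].pts) - 1)]
    total = len(segments[0].pts)
    for seg in segments[1:]:
        p = seg.pts
        if np.allclose(p[0], pts[-1][-1], atol=1e-9):
            p = p[1:]
        pts.append(p)
        total += len(p)
        names.append((seg.name, total - 1))
    template.borders.append(np.concatenate(pts))
    template.seg_names.append(names)


def _npts(cfg: SyntheticConfig, length: float, registry: dict, key: str) -> int:
    if key not in registry:
        registry[key] = max(5, int(np.ceil(length * cfg.density)) + 1)
    return registry[key]


def build_template(
    cfg: SyntheticConfig,
    area_scale: float = 1.0,
    si_scale: float = 1.0,
    registry: dict | None = None,
) -> _Template:
    """Construct the dense border layout at given fontanelle/wave scales.

    ``registry`` fixes per-segment dense point counts so that templates
    built at different scales stay in exact point correspondence.
    """
    registry = {} if registry is None else registry
    axes = cfg.half_axes
    vault = _Vault(axes)
    W = cfg.suture_widths
    d1a, d2a = (d * area_scale for d in cfg.af_diagonals)
    d1p, d2p = (d * area_scale for d in cfg.pf_diagonals)
    waves = {k: (a * si_scale, l, p) for k, (a, l, p) in cfg.interdigitation.items()}

    # midline stations (arc length from the nasion pole)
    s_nas = 2.0                       # borders start just off the pole
    s_af_front = s_nas + cfg.metopic_length
    s_af_mid = s_af_front + d1a / 2.0
    s_af_rear = s_af_front + d1a
    s_pf_front = s_af_rear + cfg.sagittal_length
    s_pf_mid = s_pf_front + d1p / 2.0
    s_pf_rear = s_pf_front + d1p
    if s_pf_rear > vault.total - 2.0:
        raise ValidationError("geometrically inconsistent config: chain exceeds vault")

    def midline(s):
        return (vault.t_at(s), 0.0)

    af_corner = vault.offset(midline(s_af_mid), 0.0, d2a / 2.0)
    pf_corner = vault.offset(midline(s_pf_mid), 0.0, d2p / 2.0)
    r_sf, r_mf = cfg.sphenoidal_radius, cfg.mastoid_radius

    # pterion: place the sphenoidal-fontanelle centre so the coronal
    # centerline (AF corner -> coronal port) has the configured length
    t_sf = vault.t_at(s_af_mid) + 0.10

    def coronal_port(c):
        return _port(vault, c, r_sf, np.rad2deg(_local_angle(vault, c, af_corner)))

    lo, hi = af_corner[1] + 0.05, np.pi / 2 + 0.35
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if vault.seg_len(af_corner, coronal_port((t_sf, mid))) < cfg.coronal_length:
            lo = mid
        else:
            hi = mid
    c_sf = (t_sf, 0.5 * (lo + hi))
    p_cor = coronal_port(c_sf)

    # asterion: squamosal centerline runs between ports facing each other
    def asterion_port(c, toward):
        return _port(vault, c, r_mf, np.rad2deg(_local_angle(vault, c, toward)))

    lo, hi = t_sf + 0.05, np.pi - 0.25
    p_sq_probe = _port(vault, c_sf, r_sf, 0.0)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if vault.seg_len(p_sq_probe,
                         asterion_port((mid, c_sf[1]), c_sf)) < cfg.squamosal_length:
            lo = mid
        else:
            hi = mid
    c_mf = (0.5 * (lo + hi), c_sf[1])

    p_sq = _port(vault, c_sf, r_sf, np.rad2deg(_local_angle(vault, c_sf, c_mf)))
    p_sq_ast = asterion_port(c_mf, c_sf)
    p_lam = _port(vault, c_mf, r_mf,
                  np.rad2deg(_local_angle(vault, c_mf, pf_corner)))
    # free-edge stub ports on the arcs facing away from the sutures
    p_ant_b1, p_ant_b5 = _free_ports(
        vault, c_sf, r_sf,
        _local_angle(vault, c_sf, af_corner), _local_angle(vault, c_sf, c_mf))
    p_inf_b5, p_inf_b7 = _free_ports(
        vault, c_mf, r_mf,
        _local_angle(vault, c_mf, c_sf), _local_angle(vault, c_mf, pf_corner))

    # centerlines (dense)
    def center(key, p0, p1):
        n = _npts(cfg, vault.seg_len(p0, p1), registry, f"c:{key}")
        return vault.seg(p0, p1, n)

    met_c = center("metopic", midline(s_nas), midline(s_af_front))
    sag_c = center("sagittal", midline(s_af_rear), midline(s_pf_front))
    cor_c = center("coronal", af_corner, p_cor)
    squ_c = center("squamosal", p_sq, p_sq_ast)
    # the lambdoid centerline starts just lateral of the sagittal end and
    # funnels open across the posterior fontanelle; the suture proper
    # begins at the flare onset (near the nominal fontanelle corner)
    p_lam_start = vault.offset(midline(s_pf_front + 2.5), 0.0, 8.0)
    lam_c = center("lambdoid", p_lam_start, p_lam)
    funnel_len = vault.seg_len(p_lam_start, pf_corner)

    xhat = np.array([1.0, 0.0, 0.0])
    refs = {"metopic": xhat, "sagittal": xhat,
            "coronal": np.array([0.0, 1.0, 0.0]),
            "squamosal": np.array([0.0, 0.0, 1.0]),
            "lambdoid": np.array([0.0, 1.0, 0.3])}

    def sides(key, c):
        a, l, ph = waves[key]
        hi_side = _side(c, +1.0, W[key], a, l, ph, refs[key], axes)
        lo_side = _side(c, -1.0, W[key], a, l, ph, refs[key], axes)
        return hi_side, lo_side

    met_R, met_L = sides("metopic", met_c)        # +x / -x
    sag_R, sag_L = sides("sagittal", sag_c)
    cor_ant, cor_post = sides("coronal", cor_c)   # anterior(frontal)/posterior
    squ_sup, squ_inf = sides("squamosal", squ_c)  # superior(parietal)/inferior
    # the lambdoid opens linearly into the posterior fontanelle; the
    # suture/fontanelle junction is the flare onset
    a_l, l_l, ph_l = waves["lambdoid"]
    s_lam = cumulative_arc_length(lam_c)
    if "k_onset" not in registry:   # shared across template variants
        registry["k_onset"] = int(np.searchsorted(s_lam, funnel_len))
    k_onset = registry["k_onset"]
    # pin the flare to reach zero exactly at the shared onset index so
    # every template variant keeps the same junction correspondence
    flare = (float(s_lam[k_onset]), cfg.pf_flare[1])
    lam_sup = _side(lam_c, +1.0, W["lambdoid"], a_l, l_l, ph_l,
                    refs["lambdoid"], axes, start_flare=flare)
    lam_inf = _side(lam_c, -1.0, W["lambdoid"], a_l, l_l, ph_l,
                    refs["lambdoid"], axes, start_flare=flare)

    def chord(key, a, b, bow=None):
        n = _npts(cfg, float(np.linalg.norm(np.asarray(a) - np.asarray(b))) + 1e-6,
                  registry, f"h:{key}")
        return vault.chord(a, b, n, bow=bow)

    pf_rear_pt = _surf(*midline(s_pf_rear), axes)
    pf_apex_pt = _surf(*midline(s_pf_front), axes)

    def b7_stub(port_pt):
        """Occipital mastoid stub: arrives at the lambdoid end
        perpendicular to the suture so the width series kinks sharply
        at JP29 regardless of the subject's latent geometry."""
        end = lam_inf[-1]
        t_hat = lam_inf[-1] - lam_inf[-4]
        t_hat = t_hat / max(np.linalg.norm(t_hat), 1e-12)
        N = end / np.array([axes[0] ** 2, axes[1] ** 2, axes[2] ** 2])
        perp = np.cross(N, t_hat)
        perp /= max(np.linalg.norm(perp), 1e-12)
        if np.dot(perp, np.asarray(port_pt) - end) < 0:
            perp = -perp
        span = float(np.linalg.norm(np.asarray(port_pt) - end))
        ctrl = end + 0.5 * span * perp
        n = _npts(cfg, span + 1e-6, registry, "h:mastoid_stub_b7_R")
        return vault.bezier(port_pt, ctrl, end, n)

    def pf_low_bow(corner, mm=3.5):
        """Bow the posterior-fontanelle lower edges away from the
        funnel apex so they never undercut the funnel gap."""
        mid = 0.5 * (np.asarray(corner, float) + pf_rear_pt)
        d = mid - pf_apex_pt
        return mm * d / max(np.linalg.norm(d), 1e-9)


    tpl = _Template()
    # border 1 (right frontal) and 2 (left frontal)
    _append_border(tpl, [
        _Segment("metopic_R", met_R),
        _Segment("af_edge_R", chord("af_edge_R", met_R[-1], cor_ant[0])),
        _Segment("coronal_ant_R", cor_ant),
        _Segment("sphen_stub_b1", chord("sphen_stub_b1", cor_ant[-1],
                                        _surf(*p_ant_b1, axes))),
    ])
    cor_ant_Lm = _mirror(cor_ant)
    _append_border(tpl, [
        _Segment("metopic_L", met_L),
        _Segment("af_edge_L", chord("af_edge_L", met_L[-1], cor_ant_Lm[0])),
        _Segment("coronal_ant_L", cor_ant_Lm),
        _Segment("sphen_stub_b2", _mirror(chord("sphen_stub_b1", cor_ant[-1],
                                                _surf(*p_ant_b1, axes)))),
    ])
    # border 3 (right parietal loop) and 4 (left)
    sq_sup_rev = squ_sup[::-1]
    cor_post_rev = cor_post[::-1]
    _append_border(tpl, [
        _Segment("sagittal_R", sag_R),
        _Segment("pf_jump_R", chord("pf_jump_R", sag_R[-1], lam_sup[0])),
        _Segment("pf_funnel_R", lam_sup[: k_onset + 1]),
        _Segment("lambdoid_sup_R", lam_sup[k_onset:]),
        _Segment("mastoid_chord_R", chord("mastoid_chord_R", lam_sup[-1],
                                          sq_sup_rev[0])),
        _Segment("squamosal_sup_R", sq_sup_rev),
        _Segment("sphen_chord_R", chord("sphen_chord_R", sq_sup_rev[-1],
                                        cor_post_rev[0])),
        _Segment("coronal_post_R", cor_post_rev),
        _Segment("af_rear_edge_R", chord("af_rear_edge_R", cor_post_rev[-1],
                                         sag_R[0])),
    ])
    lam_sup_Lm = _mirror(lam_sup)
    sq_sup_rev_Lm = _mirror(sq_sup_rev)
    cor_post_rev_Lm = _mirror(cor_post_rev)
    _append_border(tpl, [
        _Segment("sagittal_L", sag_L),
        _Segment("pf_jump_L", chord("pf_jump_L", sag_L[-1], lam_sup_Lm[0])),
        _Segment("pf_funnel_L", lam_sup_Lm[: k_onset + 1]),
        _Segment("lambdoid_sup_L", lam_sup_Lm[k_onset:]),
        _Segment("mastoid_chord_L", _mirror(chord("mastoid_chord_R", lam_sup[-1],
                                                  sq_sup_rev[0]))),
        _Segment("squamosal_sup_L", sq_sup_rev_Lm),
        _Segment("sphen_chord_L", _mirror(chord("sphen_chord_R", sq_sup_rev[-1],
                                                cor_post_rev[0]))),
        _Segment("coronal_post_L", cor_post_rev_Lm),
        _Segment("af_rear_edge_L", chord("af_rear_edge_L", cor_post_rev_Lm[-1],
                                         sag_L[0])),
    ])
    # border 5 (right temporal) and 6 (left)
    _append_border(tpl, [
        _Segment("sphen_stub_b5", chord("sphen_stub_b5", _surf(*p_ant_b5, axes),
                                        squ_inf[0])),
        _Segment("squamosal_inf_R", squ_inf),
        _Segment("mastoid_stub_b5", chord("mastoid_stub_b5", squ_inf[-1],
                                          _surf(*p_inf_b5, axes))),
    ])
    squ_inf_Lm = _mirror(squ_inf)
    _append_border(tpl, [
        _Segment("sphen_stub_b6", _mirror(chord("sphen_stub_b5",
                                                _surf(*p_ant_b5, axes), squ_inf[0]))),
        _Segment("squamosal_inf_L", squ_inf_Lm),
        _Segment("mastoid_stub_b6", _mirror(chord("mastoid_stub_b5", squ_inf[-1],
                                                  _surf(*p_inf_b5, axes)))),
    ])
    # border 7 (occipital, right asterion -> left asterion)
    lam_inf_rev = lam_inf[::-1]
    lam_inf_Lm = _mirror(lam_inf)
    _append_border(tpl, [
        _Segment("mastoid_stub_b7_R", b7_stub(_surf(*p_inf_b7, axes))),
        _Segment("lambdoid_inf_R", lam_inf[k_onset:][::-1]),
        _Segment("pf_lower_R", chord("pf_lower_R", lam_inf[k_onset], pf_rear_pt,
                                     bow=pf_low_bow(lam_inf[k_onset]))),
        _Segment("pf_lower_L", chord("pf_lower_L", pf_rear_pt,
                                     _mirror(lam_inf[k_onset]),
                                     bow=pf_low_bow(_mirror(lam_inf[k_onset])))),
        _Segment("lambdoid_inf_L", _mirror(lam_inf[k_onset:])),
        _Segment("mastoid_stub_b7_L", _mirror(b7_stub(_surf(*p_inf_b7, axes))[::-1])),
    ])

    # ground-truth suture sides (consistent direction within each pair)
    tpl.sides = {
        "metopic": (met_R, met_L), "sagittal": (sag_R, sag_L),
        "coronal_R": (cor_ant, cor_post), "coronal_L": (_mirror(cor_ant),
                                                        _mirror(cor_post)),
        "squamosal_R": (squ_sup, squ_inf), "squamosal_L": (_mirror(squ_sup),
                                                           squ_inf_Lm),
        "lambdoid_R": (lam_sup[k_onset:], lam_inf[k_onset:]),
        "lambdoid_L": (lam_sup_Lm[k_onset:], _mirror(lam_inf[k_onset:])),
    }

    ax_, ay_, az_ = axes
    tpl.landmarks = {
        "glabella": np.array([0.0, ay_, 0.0]),
        "opisthocranion": np.array([0.0, -ay_, 0.0]),
        "eurionR": np.array([ax_, 0.0, 0.0]),
        "eurionL": np.array([-ax_, 0.0, 0.0]),
        "rhinion": np.array([0.0, ay_ + 3.0, -12.0]),
        "fmoR": np.array([24.0, 0.9 * ay_, -6.0]),
        "fmoL": np.array([-24.0, 0.9 * ay_, -6.0]),
    }
    theta = np.linspace(0.0, 2 * np.pi, 513)[:-1]
    tpl.contour = np.column_stack([ax_ * np.sin(theta), ay_ * np.cos(theta),
                                   np.zeros_like(theta)])
    return tpl


#: segment-boundary -> junction-point label, per border (1-based)
_JP_BOUNDARIES = {
    1: {"metopic_R": 3, "af_edge_R": 9, "coronal_ant_R": 10},
    2: {"metopic_L": 4, "af_edge_L": 11, "coronal_ant_L": 12},
    3: {"sagittal_R": 7, "pf_funnel_R": 13, "lambdoid_sup_R": 14,
        "mastoid_chord_R": 15, "squamosal_sup_R": 16, "sphen_chord_R": 17,
        "coronal_post_R": 18},
    4: {"sagittal_L": 8, "pf_funnel_L": 19, "lambdoid_sup_L": 20,
        "mastoid_chord_L": 21, "squamosal_sup_L": 22, "sphen_chord_L": 23,
        "coronal_post_L": 24},
    5: {"sphen_stub_b5": 25, "squamosal_inf_R": 26},
    6: {"sphen_stub_b6": 27, "squamosal_inf_L": 28},
    7: {"mastoid_stub_b7_R": 29, "lambdoid_inf_R": 30, "pf_lower_L": 31,
        "lambdoid_inf_L": 32},
}


# -------------------------------------------------------- subject assembly

class _Model:
    """Template plus linear displacement fields, cached per config."""

    def __init__(self, cfg: SyntheticConfig):
        self.cfg = cfg
        registry: dict = {}
        self.base = build_template(cfg, registry=registry)
        t_area = build_template(cfg, area_scale=1.0 + cfg.area_effect,
                                registry=registry)
        t_si = build_template(cfg, si_scale=1.0 + cfg.si_effect,
                              registry=registry)
        self.X0 = self.base.all_points()
        self.D_area = t_area.all_points() - self.X0
        self.D_si = t_si.all_points() - self.X0
        self.side_base = self.base.sides
        self.side_area = t_area.sides
        self.side_si = t_si.sides
        # per-template resampled semilandmarks: the subject semilandmark
        # representation is the *linear combination of these*, because
        # arc-length resampling itself does not commute with the latent
        # displacement fields; this keeps the statistical representation
        # exactly rank-3 in the latents (noise aside)
        def _resampled(tpl):
            return np.concatenate([
                resample_border(b, cfg.counts[i])
                for i, b in enumerate(tpl.borders)
            ])
        self.S0 = _resampled(self.base)
        self.S_area = _resampled(t_area) - self.S0
        self.S_si = _resampled(t_si) - self.S0

    def subject_points(self, u: np.ndarray) -> np.ndarray:
        c = self.cfg.size_cv
        return (self.X0 * (1.0 + c * u[0])
                + u[1] * self.D_area + u[2] * self.D_si)

    def subject_semilandmarks(self, u: np.ndarray) -> np.ndarray:
        c = self.cfg.size_cv
        return (self.S0 * (1.0 + c * u[0])
                + u[1] * self.S_area + u[2] * self.S_si)

    def subject_sides(self, u: np.ndarray) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        c = self.cfg.size_cv
        out = {}
        for key in self.side_base:
            pair = []
            for j in range(2):
                s0 = self.side_base[key][j]
                pair.append(s0 * (1.0 + c * u[0])
                            + u[1] * (self.side_area[key][j] - s0)
                            + u[2] * (self.side_si[key][j] - s0))
            out[key] = tuple(pair)
        return out


_MODEL_CACHE: dict[tuple, _Model] = {}


def _model_for(cfg: SyntheticConfig) -> _Model:
    key = (cfg.half_axes, cfg.size_cv, cfg.metopic_length, cfg.sagittal_length,
           cfg.coronal_length, cfg.squamosal_length, cfg.af_diagonals,
           cfg.pf_diagonals, cfg.area_effect, tuple(sorted(cfg.suture_widths.items())),
           tuple(sorted(cfg.interdigitation.items())), cfg.si_effect,
           cfg.sphenoidal_radius, cfg.mastoid_radius, cfg.density)
    if key not in _MODEL_CACHE:
        _MODEL_CACHE[key] = _Model(cfg)
    return _MODEL_CACHE[key]


def _truth_from_dense(
    model: _Model, borders: list[np.ndarray],
    sides: dict, u: np.ndarray, cfg: SyntheticConfig, scale: float,
) -> GroundTruth:
    # junction ordinals from segment boundaries mapped through arc length
    ordinals: dict[str, tuple[int, int]] = {
        "JP1": (1, 0), "JP2": (2, 0), "JP5": (3, 0), "JP6": (4, 0),
    }
    for b, names in enumerate(model.base.seg_names, start=1):
        pts = borders[b - 1]
        s = cumulative_arc_length(pts)
        n_out = cfg.counts[b - 1]
        for name, dense_idx in names:
            jp = _JP_BOUNDARIES.get(b, {}).get(name)
            if jp is not None:
                frac = s[dense_idx] / s[-1]
                ordinals[f"JP{jp}"] = (b, int(round(frac * (n_out - 1))))

    def pair_stats(a, bpts):
        la, lb = arc_length(a), arc_length(bpts)
        w = float(np.linalg.norm(a - bpts, axis=1).mean())
        si = 0.5 * (la / np.linalg.norm(a[-1] - a[0])
                    + lb / np.linalg.norm(bpts[-1] - bpts[0]))
        return 0.5 * (la + lb), w, float(si)

    lengths, widths, sis = {}, {}, {}
    for name in SUTURE_ORDER:
        if name in ("metopic", "sagittal"):
            L, Wd, si = pair_stats(*sides[name])
        else:
            LR, WR, siR = pair_stats(*sides[f"{name}_R"])
            LL, WL, siL = pair_stats(*sides[f"{name}_L"])
            L, Wd, si = LR + LL, 0.5 * (WR + WL), 0.5 * (siR + siL)
        lengths[name], widths[name], sis[name] = float(L), float(Wd), si

    d1a, d2a = (d * (1.0 + cfg.area_effect * u[1]) * scale for d in cfg.af_diagonals)
    d1p, d2p = (d * (1.0 + cfg.area_effect * u[1]) * scale for d in cfg.pf_diagonals)
    approx_area = (d1a * d2a / 2.0 + d1p * d2p / 2.0
                   + sum(lengths[s_] * widths[s_] for s_ in SUTURE_ORDER))

    lm = model.base.landmarks
    L_cran = float(np.linalg.norm(lm["glabella"] - lm["opisthocranion"])) * scale
    W_cran = float(np.linalg.norm(lm["eurionR"] - lm["eurionL"])) * scale
    contour = model.base.contour
    C_cran = arc_length(np.vstack([contour, contour[:1]])) * scale
    return GroundTruth(
        junction_ordinals=ordinals,
        suture_length=lengths, suture_width=widths, suture_si=sis,
        cranial_length=L_cran, cranial_width=W_cran,
        cranial_circumference=C_cran,
        approx_footprint_area=float(approx_area),
        latents=np.asarray(u, dtype=float),
    )


def _smooth_noise(shape_pts: int, rng: np.random.Generator,
                  sd: float, corr_pts: float) -> np.ndarray:
    if sd == 0.0:
        rng.standard_normal((shape_pts, 3))   # keep the stream position stable
        return np.zeros((shape_pts, 3))
    sigma = max(corr_pts, 1e-6)
    pad = int(np.ceil(4 * sigma))             # avoid edge-variance inflation
    raw = rng.standard_normal((shape_pts + 2 * pad, 3))
    smoothed = gaussian_filter1d(raw, sigma=sigma, axis=0)[pad: pad + shape_pts]
    # restore unit variance analytically, then scale to the target SD
    gain = np.sqrt(2.0 * sigma * np.sqrt(np.pi))
    return sd * gain * smoothed


def generate_subject(
    cfg: SyntheticConfig,
    subject_seed: int,
    subject_id: str | None = None,
    latents: np.ndarray | None = None,
) -> SyntheticSubject:
    """One synthetic subject: border curves, landmarks and ground truth.

    Latent factors default to standard-normal draws from
    ``subject_seed``; smooth tracing noise (if configured) is applied
    after every ground-truth quantity has been measured.
    """
    rng = np.random.default_rng(subject_seed)
    u = rng.standard_normal(3) if latents is None else np.asarray(latents, float)
    u = np.clip(u, -cfg.latent_clip, cfg.latent_clip)
    model = _model_for(cfg)
    flat = model.subject_points(u)
    borders = model.base.split(flat)
    sides = model.subject_sides(u)
    scale = 1.0 + cfg.size_cv * u[0]
    truth = _truth_from_dense(model, borders, sides, u, cfg, scale)

    corr_pts = cfg.noise_corr_length * cfg.density
    noisy = [b + _smooth_noise(len(b), rng, cfg.noise_sd, corr_pts)
             for b in borders]

    sid = subject_id or f"synth-{subject_seed}"
    curves = BorderCurveSet(sid, noisy)

    # exact-linear semilandmark product, with noise at semilandmark scale
    sl_pts = model.subject_semilandmarks(u)
    start = 0
    sl_noisy = []
    for b, count in enumerate(cfg.counts):
        spacing = max(arc_length(borders[b]) / (count - 1), 1e-9)
        sl_noisy.append(sl_pts[start: start + count] + _smooth_noise(
            count, rng, cfg.noise_sd, cfg.noise_corr_length / spacing))
        start += count
    semilandmarks = SemilandmarkSet(sid, np.concatenate(sl_noisy), cfg.counts)
    lm = model.base.landmarks
    landmarks = AnatomicalLandmarks(
        rhinion=lm["rhinion"] * scale, fmoR=lm["fmoR"] * scale,
        fmoL=lm["fmoL"] * scale,
        glabella=lm["glabella"] * scale,
        opisthocranion=lm["opisthocranion"] * scale,
        eurionL=lm["eurionL"] * scale, eurionR=lm["eurionR"] * scale,
        axial_contour=model.base.contour * scale,
    )
    return SyntheticSubject(curves, landmarks, truth, semilandmarks)


def generate_population(cfg: SyntheticConfig) -> SyntheticPopulation:
    """A deterministic population; geometry is exactly linear in the
    per-subject latent draws (plus optional smooth noise)."""
    if cfg.n_subjects < 2:
        raise ValidationError("population needs >= 2 subjects")
    rng = np.random.default_rng(cfg.seed)
    subjects = []
    latents = np.empty((cfg.n_subjects, 3))
    for i in range(cfg.n_subjects):
        u = np.clip(rng.standard_normal(3), -cfg.latent_clip, cfg.latent_clip)
        latents[i] = u
        seed_i = int(rng.integers(0, 2 ** 31 - 1))
        subjects.append(
            generate_subject(cfg, seed_i, subject_id=f"synth-{i:03d}", latents=u)
        )
    return SyntheticPopulation(cfg, subjects, latents)
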