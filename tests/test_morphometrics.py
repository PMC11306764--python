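"""Suture and cranial measurements against analytic oracles."""

import numpy as np
import pytest
from scipy.integrate import quad

import suturemorph as sm
from suturemorph.morphometrics import (
    cranial_measurements,
    sinuosity_index,
    suture_length,
    suture_width,
)
from suturemorph.types import (
    AnatomicalLandmarks,
    PartRange,
    SemilandmarkSet,
    ValidationError,
)
from conftest import random_rotation


def _two_sided(points_a, points_b):
    """Pack two side polylines into a minimal landmark set + ranges."""
    n = len(points_a)
    pts = np.concatenate([
        points_a, points_b,
        *[np.column_stack([np.linspace(0, 1, c), np.full(c, 99.0 + i),
                           np.zeros(c)])
          for i, c in enumerate((n, n, n, n, n))],
    ])
    sl = SemilandmarkSet("t", pts, (n, n, n, n, n, n, n))
    ranges = [PartRange(1, 0, n - 1), PartRange(2, 0, n - 1)]
    return sl, ranges


def _line_side(length, n=100, y=0.0):
    return np.column_stack([np.linspace(0, length, n), np.full(n, y), np.zeros(n)])


class TestSutureLength:
    def test_equal_straight_sides(self):
        sl, ranges = _two_sided(_line_side(50), _line_side(50, y=2))
        assert suture_length(ranges, sl) == pytest.approx(50.0)

    def test_average_of_unequal_sides(self):
        sl, ranges = _two_sided(_line_side(60), _line_side(40, y=2))
        assert suture_length(ranges, sl) == pytest.approx(50.0)

    def test_sinusoid_against_quadrature(self):
        """Arc length of y = A sin(2 pi x / lam) over one period."""
        A, lam = 2.0, 20.0
        x = np.linspace(0, lam, 100)
        side = np.column_stack([x, A * np.sin(2 * np.pi * x / lam), 0 * x])
        true, _ = quad(lambda u: np.hypot(1, A * 2 * np.pi / lam
                                          * np.cos(2 * np.pi * u / lam)), 0, lam)
        sl, ranges = _two_sided(side, side + [0, 3, 0])
        assert suture_length(ranges, sl) == pytest.approx(true, rel=5e-3)


class TestSutureWidth:
    def test_parallel_sides_both_modes(self):
        sl, ranges = _two_sided(_line_side(50), _line_side(50, y=2))
        assert suture_width(ranges, sl, "paired") == pytest.approx(2.0)
        assert suture_width(ranges, sl, "nearest") == pytest.approx(2.0)

    def test_nearest_equals_bruteforce_average(self, rng):
        A = _line_side(30, 40)
        B = A + np.column_stack([np.zeros(40), 2 + 0.5 * np.sin(A[:, 0]),
                                 np.zeros(40)])
        sl, ranges = _two_sided(A, B)
        got = suture_width(ranges, sl, "nearest")
        pts_a = A.copy()
        pts_a[-1] = sl.border_points(1)[-1]
        brute = np.linalg.norm(
            sl.border_points(1)[:, None, :] - sl.border_points(2)[None, :, :],
            axis=2).min(axis=1).mean()
        assert got == pytest.approx(brute)

    def test_zero_width_closed_suture_accepted(self):
        side = _line_side(50)
        sl, ranges = _two_sided(side, side + [0, 1e-12, 0])
        assert suture_width(ranges, sl, "paired") == pytest.approx(0.0, abs=1e-9)

    def test_nearest_never_exceeds_paired(self, semilandmarks, partition):
        for name in ("metopic", "sagittal"):
            ranges = partition.parts[name]
            paired = suture_width(ranges, semilandmarks, "paired")
            nearest = suture_width(ranges, semilandmarks, "nearest")
            assert nearest <= paired + 1e-12

    def test_mode_mismatch_falls_back_with_warning(self, semilandmarks, partition):
        with pytest.warns(UserWarning, match="falling back"):
            suture_width(partition.parts["coronal"], semilandmarks,
                         "paired", part_name="coronal")


class TestSinuosity:
    def test_straight_suture_is_one(self):
        sl, ranges = _two_sided(_line_side(50), _line_side(50, y=2))
        assert sinuosity_index(ranges, sl) == pytest.approx(1.0, abs=1e-9)

    def test_semicircle_is_half_pi(self):
        th = np.linspace(0, np.pi, 100)
        arc = np.column_stack([5 * np.cos(th), 5 * np.sin(th), 0 * th])
        sl, ranges = _two_sided(arc, arc + [0, 0, 2])
        assert sinuosity_index(ranges, sl) == pytest.approx(np.pi / 2, rel=2e-3)

    def test_sinusoid_against_quadrature(self):
        A, lam = 1.5, 15.0
        x = np.linspace(0, 2 * lam, 200)
        side = np.column_stack([x, A * np.sin(2 * np.pi * x / lam), 0 * x])
        true, _ = quad(lambda u: np.hypot(1, A * 2 * np.pi / lam
                                          * np.cos(2 * np.pi * u / lam)), 0, 2 * lam)
        sl, ranges = _two_sided(side, side + [0, 3, 0])
        assert sinuosity_index(ranges, sl) == pytest.approx(true / (2 * lam),
                                                            rel=5e-3)

    def test_closed_curve_rejected(self):
        th = np.linspace(0, 2 * np.pi, 100)
        loop = np.column_stack([np.cos(th), np.sin(th), 0 * th])
        sl, ranges = _two_sided(loop, loop + [0, 0, 2])
        with pytest.raises(ValidationError, match="undefined SI"):
            sinuosity_index(ranges, sl)

    def test_si_at_least_one_on_real_parts(self, semilandmarks, partition):
        for name, ranges in partition.parts.items():
            if "fontanelle" in name:
                continue
            assert sinuosity_index(ranges, semilandmarks) >= 1.0 - 1e-9


def _landmarks(contour=None):
    return AnatomicalLandmarks(
        rhinion=[0, 66, -12], fmoR=[24, 56, -6], fmoL=[-24, 56, -6],
        glabella=[0, 62.7, 0], opisthocranion=[0, -62.7, 0],
        eurionL=[-53.5, 0, 0], eurionR=[53.5, 0, 0],
        axial_contour=contour,
    )


class TestCranial:
    def test_point_distance_length(self):
        L, W, C = cranial_measurements(_landmarks())
        assert L == pytest.approx(125.4)
        assert W == pytest.approx(107.0)
        assert C is None

    def test_circle_contour_circumference(self):
        r = 58.4
        th = np.linspace(0, 2 * np.pi, 2000, endpoint=False)
        contour = np.column_stack([r * np.sin(th), r * np.cos(th), 0 * th])
        lm = AnatomicalLandmarks(
            rhinion=[0, 66, -12], fmoR=[24, 56, -6], fmoL=[-24, 56, -6],
            glabella=[0, r, 0], opisthocranion=[0, -r, 0],
            eurionL=[-r, 0, 0], eurionR=[r, 0, 0], axial_contour=contour)
        _, _, C = cranial_measurements(lm)
        assert C == pytest.approx(2 * np.pi * r, rel=1e-3)

    def test_ellipse_contour_against_elliptic_integral(self):
        from scipy.special import ellipe
        a, b = 62.7, 53.5
        th = np.linspace(0, 2 * np.pi, 4000, endpoint=False)
        contour = np.column_stack([b * np.sin(th), a * np.cos(th), 0 * th])
        lm = _landmarks(contour)
        _, _, C = cranial_measurements(lm)
        e2 = 1 - (b / a) ** 2
        true = 4 * a * ellipe(e2)
        assert C == pytest.approx(true, rel=1e-3)

    def test_contour_far_from_glabella_warns(self):
        r = 40.0
        th = np.linspace(0, 2 * np.pi, 500, endpoint=False)
        contour = np.column_stack([r * np.sin(th), r * np.cos(th), 0 * th])
        with pytest.warns(UserWarning, match="axial contour"):
            cranial_measurements(_landmarks(contour))


def test_all_measures_rigid_invariant(semilandmarks, partition, subject, rng):
    R = random_rotation(rng)
    t = rng.uniform(-40, 40, 3)
    moved_sl = semilandmarks.with_points(semilandmarks.points @ R.T + t)
    moved_lm = subject.landmarks.transformed(R, t)
    for name in ("metopic", "coronal"):
        ranges = partition.parts[name]
        assert suture_length(ranges, moved_sl) == pytest.approx(
            suture_length(ranges, semilandmarks), abs=1e-9)
        assert sinuosity_index(ranges, moved_sl) == pytest.approx(
            sinuosity_index(ranges, semilandmarks), abs=1e-9)
    L0, W0, C0 = cranial_measurements(subject.landmarks)
    L1, W1, C1 = cranial_measurements(moved_lm)
    assert (L1, W1, C1) == pytest.approx((L0, W0, C0), abs=1e-9)
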