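"""Resampling and junction-point detection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import suturemorph as sm
from suturemorph.borders import (
    arc_length,
    compute_width_series,
    find_fontanelle_junction,
    find_lateral_junctions,
    resample_border,
)
from suturemorph.types import ValidationError
from conftest import random_rotation


class TestResample:
    def test_uniform_spacing_on_line(self):
        seg = np.array([[0, 0, 0], [10, 0, 0]], float)
        out = resample_border(seg, 5)
        np.testing.assert_allclose(out[:, 0], [0, 2.5, 5, 7.5, 10])

    def test_semicircle_equal_arc_spacing(self):
        """Against the analytic arc-length parametrization of a circle:
        the i-th output matches the point at arc fraction i/(n-1)."""
        th = np.linspace(0, np.pi, 1000)
        curve = np.column_stack([5 * np.cos(th), 5 * np.sin(th), 0 * th])
        out = resample_border(curve, 100)
        frac = np.linspace(0, np.pi, 100)
        analytic = np.column_stack([5 * np.cos(frac), 5 * np.sin(frac),
                                    0 * frac])
        # discretization of the input polyline bounds the error at O(h^2)
        assert np.linalg.norm(out - analytic, axis=1).max() < 1e-4
        gaps = np.linalg.norm(np.diff(out, axis=0), axis=1)
        assert np.ptp(gaps) / gaps.mean() < 5e-6

    def test_endpoints_preserved(self):
        rng = np.random.default_rng(0)
        curve = np.cumsum(rng.standard_normal((50, 3)), axis=0)
        out = resample_border(curve, 37)
        np.testing.assert_array_equal(out[0], curve[0])
        np.testing.assert_array_equal(out[-1], curve[-1])

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(2, 60), st.floats(0.5, np.pi), st.floats(1.0, 50.0))
    def test_idempotent_at_fixed_n(self, n, span, radius):
        """A polyline whose vertices are already at equal chord spacing
        (equal-angle samples of a helix) is a fixed point of resampling,
        so resample(resample(c, n), n) == resample(c, n)."""
        th = np.linspace(0, span, n)
        curve = np.column_stack([radius * np.cos(th), radius * np.sin(th),
                                 2.0 * th])
        out = resample_border(curve, n)
        assert np.abs(out - curve).max() < 1e-9
        again = resample_border(out, n)
        assert np.abs(again - out).max() < 1e-9

    def test_arc_length_converges_monotonically(self):
        th = np.linspace(0, np.pi, 2000)
        curve = np.column_stack([5 * np.cos(th), 5 * np.sin(th), 0 * th])
        total = arc_length(curve)
        errors = [total - arc_length(resample_border(curve, n))
                  for n in (25, 50, 100, 200)]
        assert all(e > 0 for e in errors)
        assert all(a > b for a, b in zip(errors, errors[1:]))
        # O(1/n^2) for a smooth curve: halving spacing quarters the error
        assert errors[-1] < errors[0] / 16

    def test_zero_length_curve_rejected(self):
        with pytest.raises(ValidationError, match="degenerate"):
            resample_border(np.zeros((1, 3)), 5)


class TestAssemble:
    def test_default_counts_give_800(self, subject):
        sl = sm.assemble_semilandmarks(subject.curves)
        assert len(sl.points) == 800
        assert sl.counts == (100, 100, 200, 200, 50, 50, 100)

    def test_custom_counts_scale_schema(self, subject):
        counts = (10, 10, 20, 20, 5, 5, 10)
        sl = sm.assemble_semilandmarks(subject.curves, counts)
        assert len(sl.points) == 80
        for b in range(1, 8):
            assert len(sl.border_points(b)) == counts[b - 1]

    def test_mismatched_counts_rejected(self, subject):
        with pytest.raises(ValidationError):
            sm.assemble_semilandmarks(subject.curves, (100, 100, 200))


class TestWidthSeries:
    def test_parallel_lines_paired(self):
        x = np.linspace(0, 9, 10)
        A = np.column_stack([x, np.zeros(10), np.zeros(10)])
        B = np.column_stack([x, np.zeros(10), np.full(10, 2.0)])
        w = compute_width_series(A, B, "paired")
        np.testing.assert_allclose(w.values, 2.0)

    def test_nearest_equals_bruteforce(self, rng):
        x = np.linspace(0, 20, 40)
        A = np.column_stack([x, np.zeros(40), np.zeros(40)])
        B = np.column_stack([x, 2 + 0.5 * np.sin(x), np.zeros(40)])
        w = compute_width_series(A, B, "nearest")
        brute = np.linalg.norm(A[:, None, :] - B[None, :, :], axis=2).min(axis=1)
        np.testing.assert_allclose(w.values, brute)

    def test_paired_requires_equal_counts(self):
        with pytest.raises(ValidationError, match="equal counts"):
            compute_width_series(np.zeros((100, 3)), np.zeros((200, 3)), "paired")


def _brute_fontanelle(w, k, ratio=10.0, start=1):
    """Direct evaluation of the stated predicate at every index."""
    hits = [i for i in range(max(1, start), len(w) - 1)
            if (w[i + 1] - w[i] > k)
            and (w[i + 1] - w[i] > ratio * k * (w[i] - w[i - 1]))]
    return hits[-1] if hits else None


class TestFontanelleJunction:
    def test_matches_bruteforce_oracle(self):
        w = np.array([1, 1, 1, 1, 1, 1, 1.5, 2.5, 4.0])
        expected = _brute_fontanelle(w, 0.15)
        assert find_fontanelle_junction(w, 0.15) == expected

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_bruteforce_agreement_random_series(self, seed):
        rng = np.random.default_rng(seed)
        w = np.abs(np.cumsum(rng.normal(0.05, 0.3, size=40))) + 0.5
        assert find_fontanelle_junction(w, 0.15) == _brute_fontanelle(w, 0.15)

    def test_constant_series_not_found(self):
        assert find_fontanelle_junction(np.full(50, 2.0), 0.15) is None

    def test_short_series_rejected(self):
        with pytest.raises(ValidationError):
            find_fontanelle_junction(np.array([1.0, 2.0]), 0.15)


class TestLateralJunctions:
    def test_single_second_difference_spike(self):
        w = np.array([1, 1, 1, 2, 3, 3, 3], float)
        # second differences [0, 1, 0, -1, 0] at i = 1..5: the single
        # positive spike sits at i = 2
        assert find_lateral_junctions(w, 0.4) == [2]

    def test_linear_ramp_has_no_junctions(self):
        w = 0.1 * np.arange(50)
        assert find_lateral_junctions(w, 0.4) == []

    def test_run_collapses_to_last_index(self):
        w = np.array([1, 1, 1, 2, 4, 7, 11, 11, 11], float)
        # indices 3..5 all spike; one junction at the run's last index
        idx = find_lateral_junctions(w, 0.4)
        assert len([i for i in idx if i <= 5]) == 1

    def test_matches_second_difference_oracle(self, rng):
        w = np.abs(np.cumsum(rng.normal(0, 0.5, 60))) + 1
        d2 = w[2:] - 2 * w[1:-1] + w[:-2]
        raw = [i + 1 for i in range(len(d2)) if d2[i] > 0.4]
        runs = []
        for i in raw:
            if runs and i == runs[-1] + 1:
                runs[-1] = i
            else:
                runs.append(i)
        assert find_lateral_junctions(w, 0.4) == runs


class TestPartition:
    def test_recovers_generator_ground_truth(self, population):
        """Every detected junction within 1 semilandmark ordinal of the
        generator's recorded truth, at default thresholds."""
        for subj in population.subjects[:4]:
            sl = sm.assemble_semilandmarks(subj.curves)
            part = sm.partition_sutures(sl)
            for jp in part.junction_points:
                border, ordinal = subj.truth.junction_ordinals[jp.label]
                assert jp.border == border
                assert abs(jp.ordinal - ordinal) <= 1, jp.label

    def test_32_junctions_9_parts(self, partition):
        assert len(partition.junction_points) == 32
        assert len(partition.parts) == 9

    def test_part_ranges_disjoint_within_border(self, partition):
        by_border = {}
        for ranges in partition.parts.values():
            for r in ranges:
                by_border.setdefault(r.border, []).append((r.start, r.stop))
        for border, spans in by_border.items():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2, f"overlap on border {border}"

    def test_rigid_invariance(self, subject, rng):
        """Widths are Euclidean distances, so junctions are unchanged by
        rigid motion of the whole subject."""
        sl = sm.assemble_semilandmarks(subject.curves)
        base = sm.partition_sutures(sl)
        R = random_rotation(rng)
        t = rng.uniform(-30, 30, 3)
        moved = sm.assemble_semilandmarks(subject.curves.transformed(R, t))
        part = sm.partition_sutures(moved)
        for a, b in zip(base.junction_points, part.junction_points):
            assert (a.border, a.ordinal) == (b.border, b.ordinal)

    def test_no_fontanelle_widening_fails_with_named_jp(self):
        """Strictly parallel borders never satisfy the width-jump
        criterion, so the metopic junction cannot be identified."""
        def line(x, n=40, z=0.0):
            return np.column_stack([np.full(n, x), np.linspace(60, 0, n),
                                    np.full(n, z)])
        curves = sm.BorderCurveSet("flat", [
            line(0.77), line(-0.77),          # metopic sides, constant gap
            line(2.7), line(-2.7),            # sagittal sides, constant gap
            line(30.0), line(-30.0), line(0.0, z=40.0),
        ])
        sl = sm.assemble_semilandmarks(curves)
        with pytest.raises(sm.PartitionFailure, match="JP3"):
            sm.partition_sutures(sl)
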