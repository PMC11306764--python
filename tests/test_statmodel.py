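"""PC-score regression, LOOCV, significance and percentile shapes."""

import warnings

import numpy as np
import pytest

import suturemorph as sm
from suturemorph.dimreduction import lmd
from suturemorph.statmodel import (
    build_feature_matrix,
    covariate_significance,
    fit_score_regression,
    fit_statistical_model,
    generate_percentile_shapes,
    loocv_evaluate,
    predict_shape,
)
from suturemorph.types import SUTURE_PARTS, MorphometricRecord, ValidationError


def _record(sid, L, W=107.0, C=367.0, S=2000.0, SI=1.1):
    return MorphometricRecord(
        subject_id=sid, cranial_length=L, cranial_width=W,
        cranial_circumference=C,
        suture_length={s: 50.0 for s in SUTURE_PARTS},
        suture_width={s: 2.0 for s in SUTURE_PARTS},
        suture_si={s: SI for s in SUTURE_PARTS},
        total_surface_area=S, average_si=SI)


@pytest.fixture(scope="module")
def size_population():
    """Noiseless single-factor population: covariates exactly affine in
    the size latent, so the linear model is exact."""
    cfg = sm.SyntheticConfig(seed=21, n_subjects=10, noise_sd=0.0,
                             area_effect=1e-9, si_effect=1e-9)
    pop = sm.generate_population(cfg)
    G0 = pop.semilandmark_matrix()
    records = [_record(s.curves.subject_id, L=s.truth.cranial_length,
                       W=s.truth.cranial_width, C=s.truth.cranial_circumference)
               for s in pop.subjects]
    partitions = [sm.partition_sutures(sl) for sl in pop.semilandmark_sets()]
    return pop, G0, records, partitions


class TestFeatures:
    def test_full_feature_set_shape(self):
        rng = np.random.default_rng(0)
        recs = [_record(f"s{i}", 120.0 + i, W=105 + rng.random(),
                        C=360 + i, S=2000 + 10 * i, SI=1.05 + 0.01 * i)
                for i in range(9)]
        F, mean, sd, names = build_feature_matrix(recs, ("L", "W", "C", "S", "SI"))
        assert F.shape == (9, 6)                      # intercept + 5 features
        assert names == ["L", "W", "C", "S", "SI"]
        np.testing.assert_allclose(F[:, 1:].mean(axis=0), 0, atol=1e-12)

    def test_single_feature_with_intercept(self):
        recs = [_record(f"s{i}", 120.0 + i) for i in range(6)]
        F, _, _, names = build_feature_matrix(recs, ("L",))
        assert F.shape == (6, 2)
        np.testing.assert_allclose(F[:, 0], 1.0)

    def test_zero_variance_covariate_rejected(self):
        recs = [_record(f"s{i}", 120.0) for i in range(5)]
        with pytest.raises(ValidationError, match="degenerate covariate"):
            build_feature_matrix(recs, ("L",))

    def test_missing_covariate_names_subject(self):
        recs = [_record("ok", 120.0), _record("broken", 121.0)]
        recs[1].cranial_circumference = None
        with pytest.raises(ValidationError, match="broken"):
            build_feature_matrix(recs, ("C",))


class TestRegression:
    def test_invertible_feature_matrix_exact(self, rng):
        F = rng.standard_normal((4, 4)) + np.eye(4) * 3
        Sk = rng.standard_normal((4, 3))
        C = fit_score_regression(Sk, F)
        np.testing.assert_allclose(C, (np.linalg.inv(F) @ Sk).T, atol=1e-9)

    def test_construct_and_recover(self, rng):
        F = np.column_stack([np.ones(20), rng.standard_normal((20, 4))])
        C0 = rng.standard_normal((6, 5))
        C = fit_score_regression(F @ C0.T, F)
        assert np.abs(C - C0).max() < 1e-10

    def test_coefficient_rmse_shrinks_with_n(self):
        rng = np.random.default_rng(17)
        C0 = rng.standard_normal((3, 3))
        rmses = []
        for n in (20, 200, 2000):
            F = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
            Sk = F @ C0.T + rng.normal(0, 0.5, (n, 3))
            C = fit_score_regression(Sk, F)
            rmses.append(np.sqrt(((C - C0) ** 2).mean()))
        assert rmses[0] > rmses[1] > rmses[2]

    def test_least_squares_beats_perturbations(self, rng):
        F = np.column_stack([np.ones(15), rng.standard_normal((15, 3))])
        Sk = rng.standard_normal((15, 4))
        C = fit_score_regression(Sk, F)
        base = np.linalg.norm(Sk - F @ C.T)
        for _ in range(25):
            C2 = C + rng.normal(0, 0.05, C.shape)
            assert base <= np.linalg.norm(Sk - F @ C2.T) + 1e-12


class TestPredict:
    def test_training_subject_recovered_in_linear_population(self, size_population):
        pop, G0, records, _ = size_population
        model = fit_statistical_model(G0, records, features=("L",), k=2)
        for i in (0, 4, 9):
            pred = predict_shape(model, records[i].covariates())
            assert lmd(pred, G0[i].reshape(-1, 3)) < 1e-6

    def test_midpoint_linearity(self, size_population):
        pop, G0, records, _ = size_population
        model = fit_statistical_model(G0, records, features=("L",), k=2)
        c1 = records[0].covariates()
        c2 = records[1].covariates()
        mid = {k: 0.5 * (c1[k] + c2[k]) for k in c1 if c1[k] is not None}
        mid["C"] = 0.5 * (c1["C"] + c2["C"])
        p_mid = predict_shape(model, mid)
        p_avg = 0.5 * (predict_shape(model, c1) + predict_shape(model, c2))
        assert np.abs(p_mid - p_avg).max() < 1e-9

    def test_extrapolation_warns(self, size_population):
        pop, G0, records, _ = size_population
        model = fit_statistical_model(G0, records, features=("L",), k=2)
        cov = records[0].covariates()
        cov["L"] = cov["L"] * 2
        with pytest.warns(UserWarning, match="extrapolat"):
            predict_shape(model, cov)


class TestLOOCV:
    def test_noiseless_linear_population_exact(self, size_population):
        pop, G0, records, partitions = size_population
        res = loocv_evaluate(G0, records, partitions, pop.config.counts,
                             features=("L",), k=2)
        assert not res.failures
        assert res.overall["lmd"].max() < 1e-6

    def test_per_part_table_has_nine_parts(self, size_population):
        pop, G0, records, partitions = size_population
        res = loocv_evaluate(G0, records, partitions, pop.config.counts,
                             features=("L",), k=2)
        assert len(res.per_part.columns) == 10   # subject_id + 9 parts

    def test_minimal_three_subjects(self, size_population):
        pop, G0, records, partitions = size_population
        res = loocv_evaluate(G0[:3], records[:3], partitions[:3],
                             pop.config.counts, features=("L",), k=1)
        assert len(res.overall) == 3

    def test_heldout_geometry_isolated(self, size_population):
        """Poisoning a subject's geometry must not change the other
        subjects' held-out predictions."""
        pop, G0, records, partitions = size_population
        clean = loocv_evaluate(G0, records, partitions, pop.config.counts,
                               features=("L",), k=2)
        poisoned = G0.copy()
        poisoned[3] += 1e3                      # geometry only; covariates kept
        dirty = loocv_evaluate(poisoned, records, partitions, pop.config.counts,
                               features=("L",), k=2)
        # subject 3's own row changes, every other row's model saw the
        # poison; but subject 3's *prediction inputs* (covariates) did
        # not change, so its row must differ only through its target
        assert dirty.overall.loc[3, "lmd"] > 100


class TestSignificance:
    def test_perfect_fit_r2_one(self):
        rng = np.random.default_rng(3)
        recs = [_record(f"s{i}", 115.0 + i + 0.1 * rng.standard_normal())
                for i in range(12)]
        L = np.array([r.cranial_length for r in recs])
        scores = np.column_stack([3.0 * L - 7.0, rng.standard_normal(12)])
        sig = covariate_significance(scores, recs, features=("L",))
        row = sig[(sig.pc == "PC1") & (sig.covariate == "L")].iloc[0]
        assert row.r2 == pytest.approx(1.0)
        assert row.p < 1e-10 and row.stars == "***"

    def test_all_column_dominates_singles(self, size_population):
        pop, G0, records, _ = size_population
        rng = np.random.default_rng(0)
        for r in records:    # decorrelate covariates so none is degenerate
            r.cranial_width += rng.normal(0, 1)
            r.total_surface_area += rng.normal(0, 10)
        model = fit_statistical_model(G0, records, features=("L", "W", "S"), k=3)
        sig = covariate_significance(model.reduced.scores, records,
                                     features=("L", "W", "S"))
        for pc in sig.pc.unique():
            sub = sig[sig.pc == pc].set_index("covariate")
            assert sub.loc["ALL", "r2"] >= sub.drop("ALL").r2.max() - 1e-9


class TestPercentiles:
    def test_five_shapes_and_self_normalization(self, size_population):
        pop, G0, records, partitions = size_population
        model = fit_statistical_model(G0, records, features=("L",), k=2)
        shapes, covs, norm = generate_percentile_shapes(
            model, records, partitions[0], pop.config.counts)
        assert sorted(shapes) == [5, 25, 50, 75, 95]
        assert all(s.shape == (800, 3) for s in shapes.values())
        np.testing.assert_allclose(norm.iloc[0].values, 1.0)

    def test_median_of_symmetric_population_near_mean_shape(self, size_population):
        pop, G0, records, partitions = size_population
        model = fit_statistical_model(G0, records, features=("L",), k=2)
        shapes, _, _ = generate_percentile_shapes(
            model, records, partitions[0], pop.config.counts, percentiles=(50,))
        mean_shape = G0.mean(axis=0).reshape(-1, 3)
        # the 50th-percentile covariate sits near the covariate mean, so
        # the predicted shape approximates the average morphology
        assert lmd(shapes[50], mean_shape) < 1.0

    def test_percentile_out_of_range_rejected(self, size_population):
        pop, G0, records, partitions = size_population
        model = fit_statistical_model(G0, records, features=("L",), k=2)
        with pytest.raises(ValidationError):
            generate_percentile_shapes(model, records, partitions[0],
                                       pop.config.counts, percentiles=(0,))
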