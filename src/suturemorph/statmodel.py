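"""Regression shape model on principal-component scores.

A linear model links each subject's PC scores to its morphometric
covariates (cranial length L, width W, circumference C, total suture
surface area S, average sinuosity index SI):

    scores_i ~ C f_i,      C = S_k F^+

with F the (standardized, intercept-augmented) feature matrix and F^+
its Moore-Penrose pseudoinverse -- the least-squares coefficient
matrix.  Predicted scores map back to geometry through the PCA basis
and the inverse standardization operator.

Evaluation is leave-one-out: the model is refitted without each
subject, the subject's own covariates drive a prediction, and location
mean deviation (overall and per suture/fontanelle part) plus predicted
vs measured suture length/width/SI quantify the error.  Per-PC,
per-covariate significance follows the OLS F test (R^2, p), with
significance stars at p < 0.001 and p < 0.0001.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .dimreduction import fit_pca, lmd, reconstruct_subject, standardize
from .morphometrics import suture_length, suture_width, sinuosity_index
from .types import (
    MorphometricRecord,
    PART_NAMES,
    RegressionShapeModel,
    SemilandmarkSet,
    SUTURE_PARTS,
    SuturePartition,
    ShapeMatrix,
    ValidationError,
)
from .morphometrics import PAIRED_WIDTH_PARTS

DEFAULT_FEATURES = ("L", "W", "C", "S", "SI")


# ---------------------------------------------------------------- features

def build_feature_matrix(
    records: list[MorphometricRecord],
    features=DEFAULT_FEATURES,
    intercept: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Column-standardized covariate matrix with optional leading
    intercept column; returns (F, mean, sd, feature_names)."""
    features = list(features)
    raw = np.empty((len(records), len(features)))
    for i, r in enumerate(records):
        cov = r.covariates()
        for j, name in enumerate(features):
            v = cov.get(name)
            if v is None or not np.isfinite(v):
                raise ValidationError(
                    f"missing covariate {name!r} for subject {r.subject_id!r}"
                )
            raw[i, j] = v
    mean = raw.mean(axis=0)
    sd = raw.std(axis=0)
    if np.any(sd == 0):
        bad = [features[j] for j in np.where(sd == 0)[0]]
        raise ValidationError(f"degenerate covariate (zero variance): {bad}")
    F = (raw - mean) / sd
    if intercept:
        F = np.column_stack([np.ones(len(F)), F])
    return F, mean, sd, features


# -------------------------------------------------------------- regression

def fit_score_regression(Sk: np.ndarray, F: np.ndarray) -> np.ndarray:
    """Least-squares coefficient matrix C (k x n_columns) via the
    Moore-Penrose pseudoinverse: score rows ~ F @ C.T."""
    Sk = np.atleast_2d(np.asarray(Sk, dtype=float))
    F = np.atleast_2d(np.asarray(F, dtype=float))
    if len(Sk) != len(F):
        raise ValidationError(f"row mismatch: scores {len(Sk)} vs features {len(F)}")
    cond = np.linalg.cond(F)
    if cond > 1e8:
        warnings.warn(f"feature matrix poorly conditioned (cond={cond:.3g})")
    C = (np.linalg.pinv(F) @ Sk).T
    return C


def fit_statistical_model(
    G0: np.ndarray,
    records: list[MorphometricRecord],
    features=DEFAULT_FEATURES,
    k: int | None = None,
    variance_threshold: float = 0.95,
    intercept: bool = True,
) -> RegressionShapeModel:
    """Standardize geometry, fit PCA (k components, or the smallest k
    reaching ``variance_threshold``), and regress scores on covariates."""
    Z = standardize(G0)
    if k is None:
        full = fit_pca(Z.G, min(len(G0) - 1, G0.shape[1]))
        cum = np.cumsum(full.explained_variance_ratio)
        k = int(np.searchsorted(cum, variance_threshold) + 1)
    pca = fit_pca(Z.G, k)
    F, mean, sd, names = build_feature_matrix(records, features, intercept)
    C = fit_score_regression(pca.scores, F)
    raw = np.array([[r.covariates()[n] for n in names] for r in records])
    return RegressionShapeModel(
        feature_names=names,
        feature_mean=mean,
        feature_sd=sd,
        intercept=intercept,
        coefficients=C,
        reduced=pca,
        standardizer=Z,
        training_range=np.stack([raw.min(axis=0), raw.max(axis=0)]),
    )


def predict_shape(
    model: RegressionShapeModel,
    covariates: dict[str, float],
) -> np.ndarray:
    """Geometry (p x 3) predicted from raw covariates; warns when a
    covariate lies outside the training range (extrapolation)."""
    raw = np.array([covariates[n] for n in model.feature_names], dtype=float)
    if model.training_range is not None:
        lo, hi = model.training_range
        out = (raw < lo) | (raw > hi)
        if out.any():
            names = [model.feature_names[j] for j in np.where(out)[0]]
            warnings.warn(f"covariates outside training range: {names} (extrapolating)")
    scores = model.coefficients @ model.design_row(covariates)
    return reconstruct_subject(model.reduced, model.standardizer, scores)


# ------------------------------------------------------------------ LOOCV

def _part_global_indices(
    partition: SuturePartition, counts: tuple[int, ...]
) -> dict[str, np.ndarray]:
    offsets = np.concatenate([[0], np.cumsum(counts)])
    out = {}
    for name, ranges in partition.parts.items():
        idx = np.concatenate(
            [offsets[r.border - 1] + r.indices() for r in ranges]
        )
        out[name] = idx.astype(int)
    return out


def _measure_predicted(
    geometry: np.ndarray,
    partition: SuturePartition,
    counts: tuple[int, ...],
    subject_id: str,
) -> dict[str, dict[str, float]]:
    sl = SemilandmarkSet(subject_id, geometry, counts)
    out = {}
    for s in SUTURE_PARTS:
        ranges = partition.parts[s]
        mode = "paired" if s in PAIRED_WIDTH_PARTS else "nearest"
        out[s] = {
            "length": suture_length(ranges, sl),
            "width": suture_width(ranges, sl, mode=mode, part_name=s),
            "si": sinuosity_index(ranges, sl),
        }
    return out


@dataclass
class LOOCVResult:
    overall: pd.DataFrame        # subject_id, lmd
    per_part: pd.DataFrame       # subject_id x 9 part columns (LMD, mm)
    morphometrics: pd.DataFrame  # measured vs predicted length/width/SI
    failures: list[str]


def loocv_evaluate(
    G0: np.ndarray,
    records: list[MorphometricRecord],
    partitions: list[SuturePartition],
    counts: tuple[int, ...],
    features=DEFAULT_FEATURES,
    k: int | None = None,
    variance_threshold: float = 0.95,
) -> LOOCVResult:
    """Leave-one-out evaluation of the regression shape model.

    Each fold refits standardization, PCA and regression on the other
    N-1 subjects, predicts the held-out subject from its true
    covariates, and scores the prediction: overall LMD, per-part LMD
    over the subject's own 9-part partition, and predicted vs measured
    suture length/width/SI.
    """
    G0 = np.asarray(G0, dtype=float)
    N = len(G0)
    if N < 3:
        raise ValidationError("LOOCV needs >= 3 subjects")
    overall_rows, part_rows, morph_rows, failures = [], [], [], []
    for i in range(N):
        rest = np.setdiff1d(np.arange(N), [i])
        try:
            model = fit_statistical_model(
                G0[rest], [records[j] for j in rest], features,
                k=k, variance_threshold=variance_threshold,
            )
            pred = predict_shape(model, records[i].covariates())
        except Exception as exc:    # noqa: BLE001 -- record failure, continue
            failures.append(f"{records[i].subject_id}: {exc}")
            continue
        truth = G0[i].reshape(-1, 3)
        overall_rows.append({"subject_id": records[i].subject_id,
                             "lmd": lmd(pred, truth)})
        part_idx = _part_global_indices(partitions[i], counts)
        part_rows.append(
            {"subject_id": records[i].subject_id,
             **{name: lmd(pred[idx], truth[idx]) for name, idx in part_idx.items()}}
        )
        measured = records[i]
        predicted = _measure_predicted(pred, partitions[i], counts,
                                       records[i].subject_id)
        for s in SUTURE_PARTS:
            morph_rows.append({
                "subject_id": records[i].subject_id, "suture": s,
                "measured_length": measured.suture_length[s],
                "predicted_length": predicted[s]["length"],
                "measured_width": measured.suture_width[s],
                "predicted_width": predicted[s]["width"],
                "measured_si": measured.suture_si[s],
                "predicted_si": predicted[s]["si"],
            })
    per_part = pd.DataFrame(part_rows)
    if not per_part.empty:
        per_part = per_part[["subject_id", *PART_NAMES]]
    return LOOCVResult(
        overall=pd.DataFrame(overall_rows),
        per_part=per_part,
        morphometrics=pd.DataFrame(morph_rows),
        failures=failures,
    )


# ------------------------------------------------------------ significance

def _stars(p: float) -> str:
    if p < 1e-4:
        return "***"
    if p < 1e-3:
        return "**"
    return ""


def covariate_significance(
    scores: np.ndarray,
    records: list[MorphometricRecord],
    features=DEFAULT_FEATURES,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """R^2 and F-test p for each PC against each covariate and ALL.

    One OLS (with intercept) per cell; no multiple-testing correction
    by default, with an optional Bonferroni factor across the table.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    F, _, _, names = build_feature_matrix(records, features, intercept=False)
    column_sets = {name: [j] for j, name in enumerate(names)}
    column_sets["ALL"] = list(range(len(names)))
    n_tests = scores.shape[1] * len(column_sets)
    rows = []
    for pc in range(scores.shape[1]):
        y = scores[:, pc]
        for col, idx in column_sets.items():
            X = sm.add_constant(F[:, idx])
            fit = sm.OLS(y, X).fit()
            p = float(fit.f_pvalue)
            if bonferroni:
                p = min(1.0, p * n_tests)
            rows.append({"pc": f"PC{pc + 1}", "covariate": col,
                         "r2": float(fit.rsquared), "p": p, "stars": _stars(p)})
    return pd.DataFrame(rows)


def significance_table(sig: pd.DataFrame) -> pd.DataFrame:
    """Pivot the tidy significance frame into a PC x covariate R^2 grid
    with significance stars appended."""
    sig = sig.assign(cell=sig["r2"].map(lambda v: f"{v:.4f}") + sig["stars"])
    table = sig.pivot(index="pc", columns="covariate", values="cell")
    order = [c for c in (*DEFAULT_FEATURES, "ALL") if c in table.columns]
    return table[order].loc[
        sorted(table.index, key=lambda s: int(s[2:]))
    ]


# -------------------------------------------------------------- percentiles

def generate_percentile_shapes(
    model: RegressionShapeModel,
    records: list[MorphometricRecord],
    partition: SuturePartition,
    counts: tuple[int, ...],
    percentiles=(5, 25, 50, 75, 95),
) -> tuple[dict[int, np.ndarray], pd.DataFrame, pd.DataFrame]:
    """Shapes of "percentile infants" plus the normalized size table.

    Each percentile's covariate vector is the elementwise (marginal)
    empirical percentile of every covariate over the training records.
    Suture lengths/widths measured on each generated shape are
    normalized by the 5th-percentile row (which therefore reads 1.0
    throughout).  Returns (shapes, covariate table, normalized sizes).
    """
    for q in percentiles:
        if not 0 < q < 100:
            raise ValidationError(f"percentile {q} outside (0, 100)")
    raw = np.array([[r.covariates()[n] for n in model.feature_names]
                    for r in records])
    shapes: dict[int, np.ndarray] = {}
    cov_rows, size_rows = [], []
    for q in percentiles:
        cov = dict(zip(model.feature_names, np.percentile(raw, q, axis=0)))
        geom = predict_shape(model, cov)
        shapes[q] = geom
        cov_rows.append({"percentile": q, **cov})
        measured = _measure_predicted(geom, partition, counts, f"p{q}")
        row = {"percentile": q}
        for s in SUTURE_PARTS:
            row[f"{s}_length"] = measured[s]["length"]
            row[f"{s}_width"] = measured[s]["width"]
        size_rows.append(row)
    sizes = pd.DataFrame(size_rows).set_index("percentile")
    normalized = sizes / sizes.iloc[0]
    return shapes, pd.DataFrame(cov_rows).set_index("percentile"), normalized
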