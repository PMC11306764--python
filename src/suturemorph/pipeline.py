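"""End-to-end pipeline orchestration.

Stages: (1) acquire subjects -- either synthetic (the generator) or
border-curve/landmark files on disk; (2) three-point rigid alignment to
a reference subject; (3) resampling to 800 semilandmarks; (4) junction
detection and 9-part partitioning; (5) morphometrics and TPS surface
area; (6) form-space GPA with bending-energy sliding; (7) dimension-
reduction comparison by 10-fold cross-validation; (8) PCA regression on
morphometric covariates with LOOCV, covariate significance, and
percentile-shape generation.

Every stage writes its outputs under ``output_dir``; the run is
deterministic for a fixed seed (byte-identical CSV outputs).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as smio
from .alignment import (
    gpa_form_space,
    rigid_align_three_points,
    slide_semilandmarks,
    transform_matrix,
)
from .borders import assemble_semilandmarks, partition_sutures
from .dimreduction import kfold_compare, standardize
from .morphometrics import measure_subject
from .statmodel import (
    covariate_significance,
    fit_statistical_model,
    generate_percentile_shapes,
    loocv_evaluate,
    significance_table,
)
from .surface import total_suture_area
from .synthetic import SyntheticConfig, generate_population
from .types import DEFAULT_COUNTS, JunctionConfig


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Pipeline configuration; defaults follow the reference protocol
    (semilandmark counts 100/100/200/200/50/50/100, junction thresholds
    k = 0.15/0.18 and m = 0.4, 0.3 mm triangulation target, 10 CV
    folds, 95 % variance threshold for the component count)."""

    seed: int = 0
    output_dir: str = "suturemorph-out"
    #: directory of per-subject <id>.csv|fcsv|json border files plus
    #: <id>.landmarks.json; None -> simulate a synthetic population
    input_dir: str | None = None
    n_subjects: int = 30
    counts: tuple[int, ...] = DEFAULT_COUNTS
    junctions: JunctionConfig = field(default_factory=JunctionConfig)
    target_edge: float = 0.3
    align_to_reference: bool = True
    slide_iterations: int = 3
    folds: int = 10
    reduction_methods: tuple = (
        "classic_pca",
        ("kernel_pca", {"kernel": "linear"}),
        ("kernel_pca", {"kernel": "cosine"}),
        ("kernel_pca", {"kernel": "rbf"}),
        ("kernel_pca", {"kernel": "sigmoid"}),
        ("kernel_pca", {"kernel": "laplacian"}),
        ("vae", {"epochs": 150}),
    )
    cv_components: int = 10
    variance_threshold: float = 0.95
    k_components: int | None = None      # overrides the variance threshold
    features: tuple[str, ...] = ("L", "W", "C", "S", "SI")
    percentiles: tuple[int, ...] = (5, 25, 50, 75, 95)
    noise_sd: float = 0.1


def _load_subjects(cfg: RunConfig):
    d = Path(cfg.input_dir)
    if not d.is_dir():
        raise FileNotFoundError(f"input path does not exist: {d}")
    subjects = []
    for curve_file in sorted(d.glob("*.curves.*")):
        sid = curve_file.name.split(".curves.")[0]
        lm_file = d / f"{sid}.landmarks.json"
        if not lm_file.exists():
            raise FileNotFoundError(f"missing landmark file: {lm_file}")
        subjects.append((smio.read_border_curves(curve_file),
                         smio.read_landmarks(lm_file)))
    if not subjects:
        raise FileNotFoundError(f"no *.curves.* files under {d}")
    return subjects


@dataclass
class PipelineResult:
    output_dir: Path
    records: list
    partitions: list
    cv_table: pd.DataFrame
    significance: pd.DataFrame
    loocv_overall: pd.DataFrame
    normalized_sizes: pd.DataFrame
    k_components: int


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    def stage(name):
        def wrap(fn):
            try:
                r = fn()
            except Exception as exc:
                raise PipelineError(name, exc) from exc
            log.append(f"stage {name}: ok")
            return r
        return wrap

    def acquire():
        if cfg.input_dir is not None:
            return _load_subjects(cfg)
        syn = SyntheticConfig(seed=cfg.seed, n_subjects=cfg.n_subjects,
                              counts=cfg.counts, noise_sd=cfg.noise_sd)
        pop = generate_population(syn)
        return [(s.curves, s.landmarks) for s in pop.subjects]

    subjects = stage("acquire")(acquire)

    def align():
        if not cfg.align_to_reference or len(subjects) < 2:
            return subjects, []
        ref = subjects[0][1]
        aligned = [subjects[0]]
        mats = [transform_matrix(np.eye(3), np.zeros(3))]
        for curves, lm in subjects[1:]:
            R, t = rigid_align_three_points(lm, ref)
            aligned.append((curves.transformed(R, t), lm.transformed(R, t)))
            mats.append(transform_matrix(R, t))
        (out / "transforms.json").write_text(
            json.dumps([m.tolist() for m in mats], indent=1))
        return aligned, mats

    subjects, _ = stage("rigid-align")(align)

    sls = stage("resample")(
        lambda: [assemble_semilandmarks(c, cfg.counts) for c, _ in subjects])

    def do_partition():
        parts = []
        for sl in sls:
            p = partition_sutures(sl, cfg.junctions)
            smio.write_partition(p, out / f"{sl.subject_id}.partition.json")
            parts.append(p)
        return parts

    partitions = stage("junctions")(do_partition)

    def measure():
        records = []
        for sl, part, (_, lm) in zip(sls, partitions, subjects):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                area = total_suture_area(sl, part, target_edge=cfg.target_edge)
            records.append(measure_subject(sl, part, lm, area.total))
        smio.write_morphometrics(records, out / "morphometrics.csv")
        return records

    records = stage("morphometrics")(measure)

    def align_slide():
        gpa = gpa_form_space(sls)
        anchors = _common_anchors(sls[0])
        slid = slide_semilandmarks(gpa.aligned, anchors,
                                   iterations=cfg.slide_iterations)
        return slid

    slid = stage("gpa-slide")(align_slide)
    G0 = np.stack([s.flat() for s in slid.shapes])

    def compare():
        tbl = kfold_compare(G0, methods=cfg.reduction_methods,
                            folds=cfg.folds, k=cfg.cv_components,
                            seed=cfg.seed)
        tbl.to_csv(out / "cv_comparison.csv")
        return tbl

    cv_table = stage("reduce-compare")(compare)

    def fit_model():
        model = fit_statistical_model(
            G0, records, features=cfg.features, k=cfg.k_components,
            variance_threshold=cfg.variance_threshold)
        sig = covariate_significance(model.reduced.scores[:, :4], records,
                                     features=cfg.features)
        sig.to_csv(out / "significance.csv", index=False)
        significance_table(sig).to_csv(out / "significance_table.csv")
        return model, sig

    model, sig = stage("regression")(fit_model)

    def evaluate():
        loo = loocv_evaluate(G0, records, partitions, cfg.counts,
                             features=cfg.features, k=model.reduced.k)
        loo.overall.to_csv(out / "loocv_overall.csv", index=False)
        loo.per_part.to_csv(out / "loocv_per_part.csv", index=False)
        loo.morphometrics.to_csv(out / "loocv_morphometrics.csv", index=False)
        return loo

    loo = stage("loocv")(evaluate)

    def percentile():
        shapes, covs, norm = generate_percentile_shapes(
            model, records, partitions[0], cfg.counts,
            percentiles=cfg.percentiles)
        covs.to_csv(out / "percentile_covariates.csv")
        norm.to_csv(out / "percentile_sizes_normalized.csv")
        data = {str(q): s.tolist() for q, s in shapes.items()}
        (out / "percentile_shapes.json").write_text(json.dumps(data))
        return norm

    norm = stage("percentiles")(percentile)

    (out / "run.log").write_text("\n".join(log) + "\n")
    return PipelineResult(
        output_dir=out, records=records, partitions=partitions,
        cv_table=cv_table, significance=sig, loocv_overall=loo.overall,
        normalized_sizes=norm, k_components=model.reduced.k,
    )


def _common_anchors(sl) -> np.ndarray:
    """Border endpoints -- the only ordinals shared by every subject."""
    off = sl.offsets
    idx = []
    for b in range(len(sl.counts)):
        idx += [int(off[b]), int(off[b + 1] - 1)]
    return np.unique(idx)
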