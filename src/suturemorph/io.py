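"""Readers and writers for border curves, landmarks and result tables.

Border curves travel in three equivalent on-disk forms:

* ``fcsv`` -- 3D Slicer Markups fiducial files (one point per row, the
  label column encoding ``border<b>-<ordinal>``).  The header's
  ``CoordinateSystem`` is honoured: LPS files are converted to the
  internal RAS-like frame (X = left->right, Y = posterior->anterior,
  Z = inferior->superior) on read.
* ``csv`` -- plain table with columns subject_id, border, ordinal, x, y, z.
* ``json`` -- a mirror of the same schema.

Morphometric records are written as one CSV row per subject with a
stable column order, and read back into validated records.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    N_BORDERS,
    AnatomicalLandmarks,
    BorderCurveSet,
    JunctionPoint,
    MorphometricRecord,
    PartRange,
    SUTURE_PARTS,
    SuturePartition,
    ValidationError,
)

_INTERNAL_FRAME = "LR-PA-IS"


# ---------------------------------------------------------------- borders

def _curves_from_rows(subject_id: str, rows) -> BorderCurveSet:
    """rows: iterable of (border, ordinal, x, y, z)."""
    by_border: dict[int, list[tuple[int, np.ndarray]]] = {}
    for border, ordinal, x, y, z in rows:
        by_border.setdefault(int(border), []).append(
            (int(ordinal), np.array([x, y, z], dtype=float))
        )
    missing = [b for b in range(1, N_BORDERS + 1) if b not in by_border]
    if missing:
        raise ValidationError(f"incomplete subject: missing border(s) {missing}")
    curves = []
    for b in range(1, N_BORDERS + 1):
        pts = [p for _, p in sorted(by_border[b], key=lambda t: t[0])]
        curves.append(np.stack(pts))
    return BorderCurveSet(subject_id, curves)


def read_border_curves(path, format: str | None = None) -> BorderCurveSet:
    """Read one subject's seven border polylines.

    ``format`` is inferred from the suffix when omitted.
    """
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "fcsv":
        return _read_fcsv(path)
    if fmt == "csv":
        return _read_csv(path)
    if fmt == "json":
        return _read_json(path)
    raise ValueError(f"unknown border-curve format {fmt!r}")


def _read_csv(path: Path) -> BorderCurveSet:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"subject_id", "border", "ordinal", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ValidationError(f"corrupt input: missing columns {required - set(df.columns)}")
    sid = str(df["subject_id"].iloc[0])
    rows = df[["border", "ordinal", "x", "y", "z"]].itertuples(index=False)
    return _curves_from_rows(sid, rows)


def _read_json(path: Path) -> BorderCurveSet:
    data = json.loads(Path(path).read_text())
    rows = []
    for b, pts in data["borders"].items():
        for i, p in enumerate(pts):
            rows.append((int(b), i, *p))
    return _curves_from_rows(str(data["subject_id"]), rows)


def _read_fcsv(path: Path) -> BorderCurveSet:
    system = "LPS"
    rows = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            if "CoordinateSystem" in line:
                val = line.split("=")[-1].strip()
                system = {"0": "RAS", "1": "LPS"}.get(val, val)
            continue
        if not line.strip():
            continue
        fields = line.split(",")
        x, y, z = (float(fields[i]) for i in (1, 2, 3))
        label = fields[11] if len(fields) > 11 else fields[-1]
        if not label.startswith("border"):
            raise ValidationError(f"corrupt input: unlabelled fcsv row {label!r}")
        b, ordinal = label[len("border"):].split("-")
        if system.upper() == "LPS":
            x, y = -x, -y
        rows.append((int(b), int(ordinal), x, y, z))
    sid = path.stem
    return _curves_from_rows(sid, rows)


def write_border_curves(curves: BorderCurveSet, path, format: str | None = None) -> Path:
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "csv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["subject_id", "border", "ordinal", "x", "y", "z"])
            for b in range(1, N_BORDERS + 1):
                for i, p in enumerate(curves.curve(b)):
                    w.writerow([curves.subject_id, b, i,
                                repr(float(p[0])), repr(float(p[1])), repr(float(p[2]))])
    elif fmt == "json":
        data = {
            "subject_id": curves.subject_id,
            "coordinate_frame": curves.coordinate_frame,
            "borders": {str(b): curves.curve(b).tolist() for b in range(1, N_BORDERS + 1)},
        }
        path.write_text(json.dumps(data))
    elif fmt == "fcsv":
        lines = [
            "# Markups fiducial file version = 4.11",
            "# CoordinateSystem = LPS",
            "# columns = id,x,y,z,ow,ox,oy,oz,vis,sel,lock,label,desc,associatedNodeID",
        ]
        n = 0
        for b in range(1, N_BORDERS + 1):
            for i, p in enumerate(curves.curve(b)):
                # write back in LPS: negate x, y
                lines.append(
                    f"p{n},{float(-p[0])!r},{float(-p[1])!r},{float(p[2])!r},"
                    f"0,0,0,1,1,1,0,border{b}-{i},,"
                )
                n += 1
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown border-curve format {fmt!r}")
    return path


# --------------------------------------------------------------- landmarks

_LM_NAMES = ("rhinion", "fmoR", "fmoL", "glabella",
             "opisthocranion", "eurionL", "eurionR")


def write_landmarks(lm: AnatomicalLandmarks, path) -> Path:
    data = {n: np.asarray(getattr(lm, n)).tolist() for n in _LM_NAMES}
    if lm.axial_contour is not None:
        data["axial_contour"] = lm.axial_contour.tolist()
    Path(path).write_text(json.dumps(data))
    return Path(path)


def read_landmarks(path) -> AnatomicalLandmarks:
    data = json.loads(Path(path).read_text())
    contour = data.get("axial_contour")
    return AnatomicalLandmarks(
        *(np.asarray(data[n], dtype=float) for n in _LM_NAMES),
        axial_contour=None if contour is None else np.asarray(contour, dtype=float),
    )


# ------------------------------------------------------------ morphometrics

def _record_columns() -> list[str]:
    cols = ["subject_id", "cranial_length", "cranial_width", "cranial_circumference"]
    for s in SUTURE_PARTS:
        cols += [f"{s}_length", f"{s}_width", f"{s}_si"]
    cols += ["total_surface_area", "average_si"]
    return cols


def write_morphometrics(records: list[MorphometricRecord], path) -> Path:
    """Write one CSV row per subject; round-trips through read_morphometrics."""
    seen = set()
    rows = []
    for r in records:
        r.__post_init__()   # revalidate in case of post-construction mutation
        if r.subject_id in seen:
            raise ValidationError(f"duplicate subject_id {r.subject_id!r}")
        seen.add(r.subject_id)
        row = {
            "subject_id": r.subject_id,
            "cranial_length": r.cranial_length,
            "cranial_width": r.cranial_width,
            "cranial_circumference": (
                "" if r.cranial_circumference is None else r.cranial_circumference
            ),
            "total_surface_area": r.total_surface_area,
            "average_si": r.average_si,
        }
        for s in SUTURE_PARTS:
            row[f"{s}_length"] = r.suture_length[s]
            row[f"{s}_width"] = r.suture_width[s]
            row[f"{s}_si"] = r.suture_si[s]
        rows.append(row)
    cols = _record_columns()
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=cols)
        w.writeheader()
        for row in rows:
            w.writerow({c: (row[c] if isinstance(row[c], str) else repr(float(row[c])))
                        if row[c] != "" else "" for c in cols})
    return Path(path)


def read_morphometrics(path) -> list[MorphometricRecord]:
    df = pd.read_csv(path, dtype={"subject_id": str},
                 float_precision="round_trip")
    records = []
    for _, row in df.iterrows():
        C = row["cranial_circumference"]
        records.append(MorphometricRecord(
            subject_id=str(row["subject_id"]),
            cranial_length=float(row["cranial_length"]),
            cranial_width=float(row["cranial_width"]),
            cranial_circumference=None if pd.isna(C) else float(C),
            suture_length={s: float(row[f"{s}_length"]) for s in SUTURE_PARTS},
            suture_width={s: float(row[f"{s}_width"]) for s in SUTURE_PARTS},
            suture_si={s: float(row[f"{s}_si"]) for s in SUTURE_PARTS},
            total_surface_area=float(row["total_surface_area"]),
            average_si=float(row["average_si"]),
        ))
    return records


# -------------------------------------------------------------- partitions

def write_partition(partition: SuturePartition, path) -> Path:
    data = {
        "junction_points": [
            {"label": jp.label, "border": jp.border, "ordinal": jp.ordinal}
            for jp in partition.junction_points
        ],
        "parts": {
            name: [{"border": r.border, "start": r.start, "stop": r.stop}
                   for r in ranges]
            for name, ranges in partition.parts.items()
        },
    }
    Path(path).write_text(json.dumps(data, indent=1))
    return Path(path)


def read_partition(path) -> SuturePartition:
    data = json.loads(Path(path).read_text())
    jps = [JunctionPoint(d["label"], d["border"], d["ordinal"])
           for d in data["junction_points"]]
    parts = {name: [PartRange(d["border"], d["start"], d["stop"]) for d in ranges]
             for name, ranges in data["parts"].items()}
    return SuturePartition(jps, parts)
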