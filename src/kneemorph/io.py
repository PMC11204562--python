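"""Readers and writers for the package's plain-text schemas.

Landmarks CSV (one row per digitized point)
    ``subject_id, side, observer_id, occasion, landmark, point_index, x, y``
    with ``point_index`` empty for single-point landmarks and a 0-based
    integer for contour points.  Parsing is strict: names must match the
    closed vocabulary exactly (no trimming), duplicates are rejected.

Angles CSV (wide, one row per subject x observer x occasion)
    ``subject_id, side, observer_id, occasion, hka_deviation, mldfa, mmpta,
    tga, ba`` — empty cells for angles not measured (partial mode).

Long value CSV
    ``subject_id, observer_id, occasion, value`` for pre-measured angles.

All writers emit UTF-8, '\n' newlines and ``repr``-precision floats, so a
write -> read -> write cycle is byte-stable.
"""
from __future__ import annotations

import csv
import io as _io
import json
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .agreement import AgreementReport, MeasurementTable
from .errors import DuplicateRowError, SchemaError, VocabularyError
from .geometry import (
    ANGLE_NAMES,
    CONTOUR_VOCABULARY,
    LANDMARK_VOCABULARY,
    AngleSet,
    LandmarkAnnotation,
    Point,
    Side,
)

__all__ = [
    "read_landmarks",
    "write_landmarks",
    "read_angles",
    "write_angles",
    "read_long_values",
    "write_long_values",
    "table_from_angles",
    "write_report_json",
    "write_plot_csv",
]

LANDMARK_COLUMNS = ["subject_id", "side", "observer_id", "occasion", "landmark", "point_index", "x", "y"]
ANGLE_COLUMNS = ["subject_id", "side", "observer_id", "occasion", *ANGLE_NAMES]
LONG_COLUMNS = ["subject_id", "observer_id", "occasion", "value"]


def _fmt(x: float) -> str:
    return repr(float(x))


def read_landmarks(path: str | Path) -> list[LandmarkAnnotation]:
    """Read and validate a Landmarks CSV into annotations.

    Row order is irrelevant; annotations are returned sorted by
    (subject_id, observer_id, occasion).

    Raises
    ------
    SchemaError
        If the header does not contain the required columns.
    VocabularyError
        If a landmark name is outside the closed vocabulary (strict match),
        naming the offending row.
    DuplicateRowError
        On duplicate (subject, observer, occasion, landmark[, index]) rows.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, header required")
        missing = [c for c in LANDMARK_COLUMNS if c != "point_index" and c not in reader.fieldnames]
        if missing:
            raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")

        points: dict[tuple, dict[str, Point]] = defaultdict(dict)
        contours: dict[tuple, dict[str, dict[int, Point]]] = defaultdict(lambda: defaultdict(dict))
        sides: dict[tuple, str] = {}
        for lineno, row in enumerate(reader, start=2):
            name = row["landmark"]
            key = (row["subject_id"], row["observer_id"], int(row["occasion"]))
            try:
                side = Side.coerce(row["side"])
            except ValueError as exc:
                raise SchemaError(f"{path} line {lineno}: invalid side {row['side']!r}") from exc
            if key in sides and sides[key] != side.value:
                raise SchemaError(f"{path} line {lineno}: inconsistent side for {key}")
            sides[key] = side.value
            try:
                pt = Point(float(row["x"]), float(row["y"]))
            except (TypeError, ValueError) as exc:
                raise SchemaError(f"{path} line {lineno}: non-numeric coordinates") from exc
            if name in LANDMARK_VOCABULARY:
                if name in points[key]:
                    raise DuplicateRowError(f"{path} line {lineno}: duplicate landmark {name!r} for {key}")
                points[key][name] = pt
            elif name in CONTOUR_VOCABULARY:
                idx_raw = row.get("point_index") or ""
                if idx_raw == "":
                    raise SchemaError(f"{path} line {lineno}: contour row {name!r} needs point_index")
                idx = int(idx_raw)
                if idx in contours[key][name]:
                    raise DuplicateRowError(
                        f"{path} line {lineno}: duplicate contour index {idx} for {name!r} {key}"
                    )
                contours[key][name][idx] = pt
            else:
                raise VocabularyError(f"{path} line {lineno}: unknown landmark name {name!r}")

    annotations = []
    for key in sorted(points.keys() | contours.keys()):
        subject_id, observer_id, occasion = key
        cont = {
            cname: [pts[i] for i in sorted(pts)]
            for cname, pts in contours.get(key, {}).items()
        }
        annotations.append(
            LandmarkAnnotation(
                subject_id=subject_id,
                side=Side(sides[key]),
                observer_id=observer_id,
                occasion=occasion,
                points=dict(sorted(points.get(key, {}).items())),
                contours=cont,
            )
        )
    return annotations


def _sorted_annotations(annotations: Iterable[LandmarkAnnotation]) -> list[LandmarkAnnotation]:
    return sorted(annotations, key=lambda a: (a.subject_id, a.observer_id, a.occasion))


def write_landmarks(annotations: Iterable[LandmarkAnnotation], path: str | Path) -> None:
    """Write annotations to a Landmarks CSV (canonical row order, byte-stable)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(LANDMARK_COLUMNS)
        for ann in _sorted_annotations(annotations):
            base = [ann.subject_id, ann.side.value, ann.observer_id, ann.occasion]
            for name in sorted(ann.points):
                p = ann.points[name]
                writer.writerow([*base, name, "", _fmt(p.x), _fmt(p.y)])
            for cname in sorted(ann.contours):
                for i, p in enumerate(ann.contours[cname]):
                    writer.writerow([*base, cname, i, _fmt(p.x), _fmt(p.y)])


def write_angles(
    rows: Sequence[tuple[LandmarkAnnotation, AngleSet]], path: str | Path
) -> None:
    """Write measured angle sets to the wide Angles CSV."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(ANGLE_COLUMNS)
        for ann, angles in sorted(
            rows, key=lambda t: (t[0].subject_id, t[0].observer_id, t[0].occasion)
        ):
            vals = [
                "" if getattr(angles, name) is None else _fmt(getattr(angles, name))
                for name in ANGLE_NAMES
            ]
            writer.writerow(
                [ann.subject_id, ann.side.value, ann.observer_id, ann.occasion, *vals]
            )


def read_angles(path: str | Path) -> pd.DataFrame:
    """Read the wide Angles CSV into a DataFrame (ids as strings)."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"subject_id": str, "observer_id": str})
    missing = [c for c in ANGLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    return df


def read_long_values(path: str | Path) -> pd.DataFrame:
    """Read a long value CSV (subject_id, observer_id, occasion, value)."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"subject_id": str, "observer_id": str})
    missing = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    return df


def write_long_values(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(LONG_COLUMNS)
        for row in df.itertuples(index=False):
            writer.writerow(
                [row.subject_id, row.observer_id, int(row.occasion), _fmt(row.value)]
            )


def table_from_angles(df: pd.DataFrame, angle_name: str) -> MeasurementTable:
    """Build a MeasurementTable for one angle from the wide Angles CSV frame."""
    if angle_name not in ANGLE_NAMES:
        raise SchemaError(f"unknown angle {angle_name!r}; expected one of {ANGLE_NAMES}")
    long_df = df[["subject_id", "observer_id", "occasion", angle_name]].rename(
        columns={angle_name: "value"}
    )
    return MeasurementTable.from_long(long_df, angle_name=angle_name)


def write_report_json(report: AgreementReport, path: str | Path) -> None:
    Path(path).write_text(report.to_json() + "\n", encoding="utf-8")


def write_plot_csv(points: pd.DataFrame, lines: Optional[dict], path: str | Path) -> None:
    """Extended Bland-Altman plot data as CSV, reference lines in a header comment."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        if lines:
            fh.write(
                "# loam_lines "
                + json.dumps({k: lines[k] for k in sorted(lines)})
                + "\n"
            )
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["subject_id", "subject_mean", "difference", "observer_id", "occasion"])
        for row in points.itertuples(index=False):
            writer.writerow(
                [
                    row.subject_id,
                    _fmt(row.subject_mean),
                    _fmt(row.difference),
                    row.observer_id,
                    int(row.occasion),
                ]
            )
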