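"""File formats: centerline CSV/JSON, rating tables, scores and reports."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .agreement import RatingTable
from .extraction import FundusImage, VesselTree
from .geometry import METRIC_NAMES, Polyline2D, TreeTortuosity

__all__ = [
    "read_image",
    "read_centerlines_csv",
    "write_centerlines_csv",
    "read_centerlines_json",
    "write_centerlines_json",
    "write_metric_report_csv",
    "read_ratings_csv",
    "write_ratings_csv",
    "read_scores_csv",
    "write_scores_csv",
    "read_labels_csv",
    "write_labels_csv",
    "write_overlay_png",
]


def read_image(path) -> FundusImage:
    """Load a PNG/TIFF/JPEG raster; RGB reduces to the green channel."""
    arr = iio.imread(path)
    return FundusImage(arr, source=str(path))


# ---------------------------------------------------------------------------
# centerlines


def write_centerlines_csv(polylines, path) -> None:
    rows = []
    for pl in polylines:
        for i, (x, y) in enumerate(pl.points):
            rows.append((pl.id, i, x, y))
    df = pd.DataFrame(rows, columns=["vessel_id", "point_index", "x", "y"])
    df.to_csv(path, index=False)


def read_centerlines_csv(path) -> list:
    df = pd.read_csv(path)
    required = {"vessel_id", "point_index", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"centerline CSV needs columns {sorted(required)}")
    out = []
    for vid, grp in df.groupby("vessel_id", sort=True):
        grp = grp.sort_values("point_index")
        out.append(Polyline2D(grp[["x", "y"]].to_numpy(), id=str(vid)))
    return out


def write_centerlines_json(polylines, path) -> None:
    payload = [
        {"vessel_id": pl.id, "points": pl.points.tolist()} for pl in polylines
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_centerlines_json(path) -> list:
    payload = json.loads(Path(path).read_text())
    return [Polyline2D(v["points"], id=str(v["vessel_id"])) for v in payload]


def write_metric_report_csv(report: TreeTortuosity, path) -> None:
    """Per-vessel metric table with one trailing TOTAL row."""
    rows = []
    for vid, vt in report.per_vessel.items():
        rows.append(
            [vid, report.weights[vid]] + [getattr(vt, m) for m in METRIC_NAMES]
        )
    total_len = float(sum(report.weights.values()))
    rows.append(["TOTAL", total_len] + [report.totals[m] for m in METRIC_NAMES])
    df = pd.DataFrame(rows, columns=["vessel_id", "length_px", *METRIC_NAMES])
    df.to_csv(path, index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# ratings / scores / labels


def write_ratings_csv(tables, path) -> None:
    """Long-format rating CSV: image_id, rater_id, round, grade."""
    rows = []
    for t in tables:
        for rater in t.raters:
            for img, grade in t.grades[rater].items():
                rows.append((img, rater, t.round, int(grade)))
    pd.DataFrame(
        rows, columns=["image_id", "rater_id", "round", "grade"]
    ).to_csv(path, index=False)


def read_ratings_csv(path, n_levels: int | None = None) -> list:
    """Load rating tables (one per round, in file order of appearance)."""
    df = pd.read_csv(path)
    required = {"image_id", "rater_id", "round", "grade"}
    if not required.issubset(df.columns):
        raise ValueError(f"ratings CSV needs columns {sorted(required)}")
    tables = []
    for rnd in df["round"].drop_duplicates():
        sub = df[df["round"] == rnd]
        wide = sub.pivot(index="image_id", columns="rater_id", values="grade")
        if wide.isna().any().any():
            raise ValueError(f"round {rnd!r}: missing ratings for some images")
        wide = wide.astype(int).sort_index()
        wide = wide[sorted(wide.columns)]
        levels = n_levels if n_levels is not None else int(wide.to_numpy().max()) + 1
        tables.append(
            RatingTable(grades=wide, round=str(rnd), n_levels=max(levels, 2))
        )
    return tables


def write_scores_csv(scores: pd.DataFrame, path) -> None:
    """Scores table: image_id index, one column per metric."""
    long = scores.reset_index().melt(
        id_vars="image_id", var_name="metric", value_name="value"
    )
    long.to_csv(path, index=False, float_format="%.8g")


def read_scores_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"image_id", "metric", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"scores CSV needs columns {sorted(required)}")
    return df.pivot(index="image_id", columns="metric", values="value").sort_index()


def write_labels_csv(labels: pd.Series, path) -> None:
    df = labels.rename("class").rename_axis("image_id").reset_index()
    df.to_csv(path, index=False)


def read_labels_csv(path) -> pd.Series:
    df = pd.read_csv(path)
    required = {"image_id", "class"}
    if not required.issubset(df.columns):
        raise ValueError(f"labels CSV needs columns {sorted(required)}")
    return df.set_index("image_id")["class"].astype(int).sort_index()


def write_overlay_png(image: FundusImage, tree: VesselTree, path) -> None:
    """Inspection overlay: extracted centerlines in red over the image."""
    img = image.raster
    lo, hi = float(img.min()), float(img.max())
    scale = 255.0 / (hi - lo) if hi > lo else 1.0
    gray = ((img - lo) * scale).astype(np.uint8)
    rgb = np.stack([gray, gray, gray], axis=-1)
    for seg in tree.segments:
        cols = np.clip(np.round(seg.points[:, 0]).astype(int), 0, img.shape[1] - 1)
        rows = np.clip(np.round(seg.points[:, 1]).astype(int), 0, img.shape[0] - 1)
        rgb[rows, cols] = (255, 0, 0)
    iio.imwrite(path, rgb)
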