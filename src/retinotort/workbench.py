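"""Desk-scale study orchestration: measure -> agreement -> ROC, one bundle.

:func:`run_study` replays the structure of a multi-expert tortuosity
validation study end to end: whole-retina tortuosity scores per image (from
an image directory, a scores file, or freshly generated phantoms), the
rating-panel agreement analysis, and ROC validation of every metric against
a binary consensus reference, writing a deterministic ``report.json`` plus
per-table CSVs.

In fully synthetic mode each image's latent tortuosity grade drives both the
rendered phantom (amplitude/inflection count grow with grade) and the
simulated raters' votes, so the prognostic analysis is exercised under a
known ground truth.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from .agreement import (
    GROUPINGS,
    RatingTable,
    group_grades,
    kappa_matrix,
    majority_vote,
    consensus_summary,
)
from .extraction import ExtractionConfig, measure_image
from .geometry import METRIC_NAMES
from .synthetic import (
    PanelSpec,
    banded_confusion,
    phantom_scene,
    render_phantom,
    simulate_panel,
)
from .validation import ROCCurve, expert_roc_point, roc_curve

logger = logging.getLogger(__name__)

__all__ = ["StudyConfig", "StudyReport", "ReconciliationError", "run_study"]


class ReconciliationError(ValueError):
    """Image identifiers of ratings and scores do not match."""


@dataclass(frozen=True)
class StudyConfig:
    """Single source of truth for one study run.

    Exactly one score source is used: ``scores_csv`` if given, else
    ``images_dir``, else phantoms are generated (``n_images`` of them).
    Ratings come from ``ratings_csv`` or a simulated panel; the ROC
    reference from ``labels_csv`` or, flagged in provenance, the pooled
    majority vote under ``tie_rule``.
    """

    seed: int = 0
    n_images: int = 12
    n_vessels: int = 3
    shape: tuple = (256, 256)
    noise_sd: float = 0.01
    rater_accuracies: tuple = (0.94, 0.90, 0.86, 0.82, 0.78)
    rounds: tuple = ("R1", "R2")
    grouping: str = "asymptomatic"
    tie_rule: str = "higher"
    images_dir: str | None = None
    ratings_csv: str | None = None
    scores_csv: str | None = None
    labels_csv: str | None = None
    out_dir: str | None = None
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)

    @staticmethod
    def from_toml(path) -> "StudyConfig":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        if "extraction" in data:
            ex = data.pop("extraction")
            metric = ex.pop("metric", None)
            if "scales" in ex:
                ex["scales"] = tuple(ex["scales"])
            from .geometry import MetricConfig

            cfg = ExtractionConfig(
                **{**ex, **({"metric": MetricConfig(**metric)} if metric else {})}
            )
            data["extraction"] = cfg
        for key in ("shape", "rounds", "rater_accuracies"):
            if key in data:
                data[key] = tuple(data[key])
        return StudyConfig(**data)


@dataclass(frozen=True)
class StudyReport:
    scores: pd.DataFrame
    tables: tuple
    labels: pd.Series
    kappa: pd.DataFrame
    consensus: dict
    curves: dict
    expert_points: tuple
    report: dict


def _round_sig(value, sig: int = 6):
    if isinstance(value, dict):
        return {k: _round_sig(v, sig) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_round_sig(v, sig) for v in value]
    if isinstance(value, (float, np.floating)):
        v = float(value)
        if not np.isfinite(v):
            return None
        return float(f"{v:.{sig}g}")
    if isinstance(value, (int, np.integer)):
        return int(value)
    return value


def _config_hash(config: StudyConfig) -> str:
    fields = dataclasses.asdict(config)
    fields.pop("out_dir", None)  # output location does not shape the results
    payload = json.dumps(fields, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _synthetic_inputs(config: StudyConfig):
    """Phantom scores and a grade-conditioned rating panel, all seeded."""
    n = config.n_images
    root = np.random.SeedSequence(config.seed)
    grade_seed, panel_seed, *img_seeds = [
        int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(n + 2)
    ]
    rng = np.random.default_rng(grade_seed)
    true_grades = rng.choice(4, size=n)
    image_ids = [f"img_{i:03d}" for i in range(n)]
    rows = {}
    dropped = {}
    for i, (img_id, grade) in enumerate(zip(image_ids, true_grades)):
        specs = phantom_scene(
            n_vessels=config.n_vessels,
            shape=config.shape,
            seed=img_seeds[i],
            grade=int(grade),
        )
        phantom = render_phantom(
            specs, shape=config.shape, noise_sd=config.noise_sd, seed=img_seeds[i]
        )
        result = measure_image(phantom.raster, config.extraction)
        rows[img_id] = [result.totals[m] for m in METRIC_NAMES]
        if result.dropped:
            dropped[img_id] = list(result.dropped)
    scores = pd.DataFrame.from_dict(
        rows, orient="index", columns=list(METRIC_NAMES)
    )
    scores.index.name = "image_id"
    raters = {
        f"E{i + 1}": banded_confusion(acc, 4)
        for i, acc in enumerate(config.rater_accuracies)
    }
    panel = simulate_panel(
        PanelSpec(
            n_images=n,
            raters=raters,
            rounds=tuple(config.rounds),
            seed=panel_seed,
        ),
        true_grades=true_grades,
    )
    return scores, list(panel.tables), dropped


def run_study(config: StudyConfig) -> StudyReport:
    """Execute measure -> agreement -> ROC and return/write the bundle.

    Re-running with identical config and inputs produces a bit-identical
    ``report.json``.  Raises :class:`ReconciliationError` when rating and
    score image ids differ, naming the offenders.
    """
    grouping = GROUPINGS[config.grouping]
    dropped: dict = {}
    synthetic_ratings = None
    if config.scores_csv:
        scores = rio.read_scores_csv(config.scores_csv)
    elif config.images_dir:
        rows = {}
        paths = sorted(Path(config.images_dir).glob("*"))
        paths = [p for p in paths if p.suffix.lower() in (".png", ".tif", ".tiff", ".jpg", ".jpeg")]
        for p in paths:
            result = measure_image(rio.read_image(p), config.extraction)
            rows[p.stem] = [result.totals[m] for m in METRIC_NAMES]
            if result.dropped:
                dropped[p.stem] = list(result.dropped)
        scores = pd.DataFrame.from_dict(rows, orient="index", columns=list(METRIC_NAMES))
        scores.index.name = "image_id"
    else:
        scores, synthetic_ratings, dropped = _synthetic_inputs(config)

    if config.ratings_csv:
        tables = rio.read_ratings_csv(config.ratings_csv)
    elif synthetic_ratings is not None:
        tables = synthetic_ratings
    else:
        raise ReconciliationError(
            "no ratings available: provide ratings_csv or run in synthetic mode"
        )

    score_ids = set(scores.index)
    rating_ids = set(tables[0].images)
    if score_ids != rating_ids:
        only_scores = sorted(score_ids - rating_ids)
        only_ratings = sorted(rating_ids - score_ids)
        raise ReconciliationError(
            f"image id mismatch: only in scores {only_scores}, "
            f"only in ratings {only_ratings}"
        )

    binary_tables = [
        group_grades(t, grouping) if t.n_levels > 2 else t for t in tables
    ]
    consensus = {
        t.round: {
            "four_grade" if t.n_levels > 2 else "binary": consensus_summary(t),
            grouping.name: consensus_summary(bt),
        }
        for t, bt in zip(tables, binary_tables)
    }

    if config.labels_csv:
        labels = rio.read_labels_csv(config.labels_csv)
        label_source = "labels_csv"
        vote = None
    else:
        vote = majority_vote(binary_tables, tie_rule=config.tie_rule)
        labels = vote.labels
        label_source = f"majority_vote({vote.source}, tie_rule={config.tie_rule})"
    labels = labels.loc[sorted(scores.index)].astype(int)

    kappa = kappa_matrix(binary_tables, consensus=labels, tie_rule=config.tie_rule)

    curves: dict = {}
    for m in METRIC_NAMES:
        curves[m] = roc_curve(
            scores.loc[labels.index, m].to_numpy(), labels.to_numpy()
        )
    expert_points = tuple(
        expert_roc_point(
            t.grades[r].to_numpy(), labels.loc[t.images].to_numpy(),
            rater=r, round=t.round,
        )
        for t in binary_tables
        for r in t.raters
    )

    report = {
        "provenance": {
            "package": "retinotort",
            "config_hash": _config_hash(config),
            "seed": config.seed,
            "label_source": label_source,
            "grouping": grouping.name,
        },
        "n_images": int(scores.shape[0]),
        "metrics": list(METRIC_NAMES),
        "auc": {m: curves[m].auc for m in METRIC_NAMES},
        "expert_points": [
            {
                "rater": p.rater,
                "round": p.round,
                "sensitivity": p.sensitivity,
                "specificity": p.specificity,
            }
            for p in expert_points
        ],
        "consensus_pct": {
            rnd: {name: {str(k): v for k, v in summ.items()} for name, summ in d.items()}
            for rnd, d in consensus.items()
        },
        "kappa": {
            a: {b: (None if np.isnan(k) else k) for b, k in row.items()}
            for a, row in kappa.to_dict(orient="index").items()
        },
        "majority_ties": int(vote.ties.sum()) if vote is not None else 0,
        "dropped_vessels": dropped,
    }
    report = _round_sig(report)

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(report, sort_keys=True, indent=1) + "\n"
        )
        rio.write_scores_csv(scores, out / "scores.csv")
        rio.write_labels_csv(labels, out / "labels.csv")
        kappa.round(6).to_csv(out / "kappa_matrix.csv")
        rio.write_ratings_csv(tables, out / "ratings.csv")
        if vote is not None:
            pd.DataFrame(
                {"label": vote.labels, "tie": vote.ties}
            ).rename_axis("image_id").to_csv(out / "majority_labels.csv")
        for m, curve in curves.items():
            pd.DataFrame(
                {
                    "threshold": curve.thresholds,
                    "fpr": curve.fpr,
                    "tpr": curve.tpr,
                }
            ).to_csv(out / f"roc_{m}.csv", index=False, float_format="%.6g")

    return StudyReport(
        scores=scores,
        tables=tuple(tables),
        labels=labels,
        kappa=kappa,
        consensus=consensus,
        curves=curves,
        expert_points=expert_points,
        report=report,
    )
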