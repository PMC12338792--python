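"""Orchestration: simulate a study, calibrate, analyze every volume, and run
the statistics — with structured logging of calibration constants and
per-volume QC counts so every surrogate threshold is auditable."""

from __future__ import annotations

import json
import logging
from collections import defaultdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .attenuation import measure_attenuation
from .config import PipelineConfig
from .errors import SegmentationError, SkinOctError, ValidationError
from .io import (
    GROUPS,
    OctVolume,
    StudyRecord,
    read_annotations,
    read_study_table,
    read_volume,
)
from .preprocess import CalibrationReference, average_volume, calibrate
from .segmentation import measure_thickness, segment_volume
from .stats import (
    MetricSeries,
    longitudinal_summary,
    results_table,
    run_comparison_plan,
)
from .study import generate_study

log = logging.getLogger("skinoct")


def run_simulate(config: PipelineConfig) -> Path:
    """Generate a volume-backed synthetic study under ``config.out_dir``.

    Deterministic under a fixed seed; emits volumes, ground truth, flat
    calibration references with annotations, and the study table.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table_path, records = generate_study(
        out,
        seed=config.seed,
        n_mice=config.n_mice,
        months=tuple(range(config.n_months)),
        phantom_overrides={
            "n_ascans_per_bscan": config.n_ascans_per_bscan,
            "n_bscans": config.n_bscans,
            "n_axial": config.n_axial,
        },
    )
    log.info("simulated %d study records under %s", len(records), out)
    return table_path


def calibrate_from_annotations(
    annotations_path: str | Path, config: PipelineConfig
) -> CalibrationReference:
    """Build the calibration from an annotations JSON whose ``volume_id``
    fields are volume paths."""
    annotations = read_annotations(annotations_path)
    by_volume: dict[str, list] = defaultdict(list)
    for ann in annotations:
        by_volume[ann.volume_id].append(ann)
    refs = [(read_volume(path), anns) for path, anns in by_volume.items()]
    cal = calibrate(
        refs,
        prominence_multiplier=config.prominence_multiplier,
        prominence_value=config.prominence_value,
    )
    log.info(
        "calibration: air_mean=%.3f muscle_mean=%.3f prominence=%.3f (%d volumes)",
        cal.air_mean,
        cal.muscle_mean,
        cal.prominence_threshold,
        len(refs),
    )
    return cal


def analyze_volume(
    volume: OctVolume, cal: CalibrationReference, config: PipelineConfig
) -> dict:
    """Per-volume metrics: mean skin thickness (um) and mean attenuation
    coefficient (mm^-1) with QC counts."""
    averaged = average_volume(volume, config.window, config.edge_trim)
    columns, profiles = segment_volume(averaged, cal)
    thickness = measure_thickness(
        profiles, volume.axial_pitch, config.refractive_index
    )
    atten = measure_attenuation(
        columns,
        profiles,
        volume.axial_pitch,
        volume.scale,
        min_points=config.min_fit_points,
        roi_trim_start=config.roi_trim_start,
        roi_trim_end=config.roi_trim_end,
    )
    return {
        "n_total": thickness.n_total,
        "n_valid_thickness": thickness.n_valid,
        "n_valid_mu": atten.n_valid,
        "thickness_um": thickness.volume_mean,
        "mu_mm_inv": atten.volume_mean,
    }


def run_analyze(
    config: PipelineConfig,
    table_path: str | Path,
    annotations_path: str | Path | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Analyze every study record and run the statistical comparison plan.

    An unreadable volume aborts the run naming the record; a volume whose
    segmentation fails entirely is recorded as missing and the run
    continues. Writes ``metrics.csv``, per-metric comparison tables and a
    JSON report under ``out_dir``.
    """
    table_path = Path(table_path)
    out = Path(out_dir) if out_dir is not None else table_path.parent / "analysis"
    out.mkdir(parents=True, exist_ok=True)
    records = read_study_table(table_path)
    if annotations_path is None:
        annotations_path = table_path.parent / "references" / "annotations.json"
    cal = calibrate_from_annotations(annotations_path, config)

    rows = []
    for rec in records:
        try:
            volume = read_volume(rec.volume_path)
        except (OSError, SkinOctError) as exc:
            raise SkinOctError(
                f"unreadable volume for record mouse={rec.mouse_id} "
                f"site={rec.site} month={rec.month}: {exc}"
            ) from exc
        row = {
            "mouse_id": rec.mouse_id,
            "group": rec.group,
            "site": rec.site,
            "month": rec.month,
            "volume_path": rec.volume_path,
        }
        try:
            row.update(analyze_volume(volume, cal, config))
            log.info(
                "%s: n_valid=%d/%d thickness=%.1f um mu=%.2f mm^-1",
                rec.volume_path,
                row["n_valid_thickness"],
                row["n_total"],
                row["thickness_um"],
                row["mu_mm_inv"],
            )
        except SegmentationError as exc:
            log.warning("segmentation failed for %s: %s", rec.volume_path, exc)
            row.update(
                {
                    "n_total": 0,
                    "n_valid_thickness": 0,
                    "n_valid_mu": 0,
                    "thickness_um": np.nan,
                    "mu_mm_inv": np.nan,
                }
            )
        rows.append(row)
    metrics = pd.DataFrame(rows)
    metrics.to_csv(out / "metrics.csv", index=False)

    report: dict = {
        "calibration": {
            "air_mean": cal.air_mean,
            "muscle_mean": cal.muscle_mean,
            "prominence_threshold": cal.prominence_threshold,
        },
        "n_volumes": len(records),
        "metrics": {},
    }
    months_present = set(metrics["month"].unique())
    for metric in ("thickness_um", "mu_mm_inv"):
        sub = metrics.dropna(subset=[metric])[
            ["mouse_id", "group", "site", "month"]
        ].copy()
        sub["value"] = metrics.dropna(subset=[metric])[metric]
        series = MetricSeries(metric=metric, records=sub)
        entry: dict = {}
        if sub["month"].nunique() >= 2:
            means, trends = longitudinal_summary(series)
            means.to_csv(out / f"{metric}_monthly_means.csv", index=False)
            trends.to_csv(out / f"{metric}_trends.csv", index=False)
            entry["trends"] = trends.to_dict(orient="records")
        if {0, 7} <= months_present:
            comparisons = run_comparison_plan(series, config.alpha, config.iqr_k)
            ctab = results_table(comparisons)
            ctab.to_csv(out / f"{metric}_comparisons.csv", index=False)
            entry["comparisons"] = ctab.to_dict(orient="records")
            entry["significant_sites"] = sorted(
                {
                    r.site
                    for r in comparisons
                    if r.test == "anova" and r.months == (7,) and r.p_value < config.alpha
                }
            )
        report["metrics"][metric] = entry
    (out / "report.json").write_text(json.dumps(report, indent=1, default=float))
    return report
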