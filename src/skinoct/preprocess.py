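"""A-scan block averaging, edge trimming, and reference-intensity calibration.

Each B-scan is downsized by averaging consecutive sets of raw A-scan columns
(default 10, trailing partial block included — the convention under which a
1355-column B-scan yields 136 averaged columns and, after trimming 15 from
each end, the 106 usable columns the analysis counts on). Averaging operates
on the stored log-scale values by default.

Calibration pools annotated air and muscle voxels over a set of reference
volumes to produce the noise floor (air mean), the dermis-muscle boundary
threshold (muscle mean) and the peak-prominence threshold (by default 3x the
air-region standard deviation, a reproducible surrogate for a manually
chosen value).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import CalibrationError, ValidationError
from .io import OctVolume, RegionAnnotation, extract_region


@dataclass
class AveragedBScan:
    """A B-scan after column averaging (and possibly edge trimming)."""

    intensity: np.ndarray  # (axial, averaged column)
    n_raw_per_column: int
    trimmed: int
    axial_pitch: float

    @property
    def n_columns(self) -> int:
        return self.intensity.shape[1]


@dataclass
class CalibrationReference:
    """Reference intensities derived from annotated volumes (log units)."""

    air_mean: float
    muscle_mean: float
    prominence_threshold: float
    source_volumes: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.air_mean < self.muscle_mean:
            raise CalibrationError(
                f"air mean ({self.air_mean:.3f}) must be below muscle mean "
                f"({self.muscle_mean:.3f})"
            )
        if not self.prominence_threshold > 0:
            raise CalibrationError("prominence threshold must be positive")


def average_columns(
    bscan: np.ndarray, window: int, axial_pitch: float = 1.0
) -> AveragedBScan:
    """Block-average raw A-scan columns in sets of ``window``.

    Output column ``j`` is the arithmetic mean of raw columns
    ``[j*window, min((j+1)*window, n_raw))``; the trailing partial block is
    kept. A window larger than the column count yields a single column.
    """
    bscan = np.asarray(bscan, dtype=float)
    if bscan.ndim != 2:
        raise ValidationError(f"bscan must be 2-D, got shape {bscan.shape}")
    if window < 1:
        raise ValidationError("averaging window must be >= 1")
    n_raw = bscan.shape[1]
    starts = np.arange(0, n_raw, window)
    sums = np.add.reduceat(bscan, starts, axis=1)
    counts = np.diff(np.append(starts, n_raw))
    return AveragedBScan(
        intensity=sums / counts,
        n_raw_per_column=window,
        trimmed=0,
        axial_pitch=axial_pitch,
    )


def trim_edges(averaged: AveragedBScan, n_trim: int) -> AveragedBScan:
    """Drop the first and last ``n_trim`` averaged columns (low-intensity
    scan edges)."""
    if n_trim < 0:
        raise ValidationError("n_trim must be >= 0")
    n = averaged.n_columns
    if 2 * n_trim >= n:
        raise ValidationError(
            f"trimming {n_trim} columns from each end of {n} would leave nothing"
        )
    sl = slice(n_trim, n - n_trim) if n_trim else slice(None)
    return AveragedBScan(
        intensity=averaged.intensity[:, sl],
        n_raw_per_column=averaged.n_raw_per_column,
        trimmed=averaged.trimmed + n_trim,
        axial_pitch=averaged.axial_pitch,
    )


def average_volume(
    volume: OctVolume, window: int = 10, n_trim: int = 15
) -> list[AveragedBScan]:
    """Averaged, trimmed B-scans of a volume (one entry per B-scan)."""
    return [
        trim_edges(
            average_columns(volume.intensity[:, :, b], window, volume.axial_pitch),
            n_trim,
        )
        for b in range(volume.n_bscans)
    ]


def calibrate(
    references: Sequence[tuple[OctVolume, Sequence[RegionAnnotation]]],
    prominence_multiplier: float = 3.0,
    prominence_value: float | None = None,
) -> CalibrationReference:
    """Pool annotated air/muscle regions across reference volumes.

    Every reference volume must carry at least one air and one muscle
    annotation, with the air region shallower than the muscle region.
    ``prominence_value``, when given, overrides the default rule
    (``prominence_multiplier`` times the pooled air-region standard
    deviation) — useful for noiseless data where that standard deviation
    vanishes.
    """
    if not references:
        raise CalibrationError("no reference volumes supplied")
    air_vox, muscle_vox, sources = [], [], []
    for volume, annotations in references:
        airs = [a for a in annotations if a.region == "air"]
        muscles = [a for a in annotations if a.region == "muscle"]
        if not airs or not muscles:
            raise CalibrationError(
                "each reference volume needs one air and one muscle annotation"
            )
        for a in airs:
            for m in muscles:
                if not a.axial[1] <= m.axial[0]:
                    raise CalibrationError(
                        "air region must be shallower than the muscle region"
                    )
        for ann in airs:
            air_vox.append(np.ravel(extract_region(volume, ann)))
        for ann in muscles:
            muscle_vox.append(np.ravel(extract_region(volume, ann)))
        sources.append(volume.source_id)
    air = np.concatenate(air_vox)
    muscle = np.concatenate(muscle_vox)
    if air.size == 0 or muscle.size == 0:
        raise CalibrationError("annotated region is empty")
    if prominence_value is not None:
        prominence = float(prominence_value)
    else:
        prominence = prominence_multiplier * float(air.std())
        if prominence <= 0:
            raise CalibrationError(
                "air-region standard deviation is zero; pass an explicit "
                "prominence_value"
            )
    return CalibrationReference(
        air_mean=float(air.mean()),
        muscle_mean=float(muscle.mean()),
        prominence_threshold=prominence,
        source_volumes=sources,
    )
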