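"""Per-A-scan detection of the skin surface, the DEJ, and the dermis-muscle
boundary, and the skin-thickness measurement built on them.

The surface is the first local maximum above the air noise floor whose
topographic prominence clears the calibration threshold; the DEJ is the
second such peak. The dermis-muscle boundary is where the depth profile
first drops below the muscle mean intensity — with the search starting only
once the profile has descended off the surface peak's flank, so the dark
trough just below a bright surface cannot masquerade as muscle. Columns
where any of the three landmarks is missing or out of order are flagged
invalid and excluded from volume means (reported via n_valid/n_total).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from .errors import SegmentationError, ValidationError
from .preprocess import AveragedBScan, CalibrationReference


@dataclass(frozen=True)
class BoundaryProfile:
    """Landmark axial indices for one averaged A-scan (None = not found)."""

    surface_idx: int | None
    dej_idx: int | None
    muscle_idx: int | None
    valid: bool


@dataclass
class ThicknessResult:
    """Per-volume skin thickness (um): per-column values over valid columns,
    their mean, and the QC counts."""

    per_ascan: np.ndarray
    volume_mean: float
    n_valid: int
    n_total: int


def detect_peaks(
    column: np.ndarray, noise_floor: float, prominence: float
) -> list[int]:
    """Local maxima above ``noise_floor`` with prominence >= threshold,
    shallowest first; a flat plateau reports its shallowest index."""
    column = np.asarray(column, dtype=float)
    if not np.all(np.isfinite(column)):
        raise ValidationError("profile contains non-finite values")
    if not prominence > 0:
        raise ValidationError("prominence must be positive")
    peaks, props = find_peaks(column, plateau_size=(1, None), prominence=prominence)
    left = props["left_edges"]
    return [int(i) for i in left if column[i] > noise_floor]


def detect_muscle_boundary(
    column: np.ndarray,
    surface_idx: int,
    muscle_mean: float,
    descent: float,
) -> int | None:
    """First axial index past the surface peak's falling edge where the
    intensity drops below ``muscle_mean``.

    The search begins at the first index after ``surface_idx`` whose value
    has fallen at least ``descent`` (the prominence threshold) below the
    surface-peak value. Returns None when no such crossing exists.
    """
    column = np.asarray(column, dtype=float)
    if not 0 <= surface_idx < column.size:
        raise ValidationError("surface_idx outside the profile")
    below_flank = np.nonzero(
        column[surface_idx + 1 :] < column[surface_idx] - descent
    )[0]
    if below_flank.size == 0:
        return None
    start = surface_idx + 1 + int(below_flank[0])
    crossing = np.nonzero(column[start:] < muscle_mean)[0]
    if crossing.size == 0:
        return None
    return start + int(crossing[0])


def segment_column(
    column: np.ndarray, cal: CalibrationReference
) -> BoundaryProfile:
    """Locate surface, DEJ and muscle boundary in one averaged A-scan.

    An unresolvable column (fewer than two peaks, no boundary crossing, or
    landmarks out of order) yields ``valid=False`` — data, not an error.
    """
    peaks = detect_peaks(column, cal.air_mean, cal.prominence_threshold)
    surface = peaks[0] if len(peaks) >= 1 else None
    dej = peaks[1] if len(peaks) >= 2 else None
    muscle = (
        detect_muscle_boundary(
            column, surface, cal.muscle_mean, cal.prominence_threshold
        )
        if surface is not None
        else None
    )
    valid = (
        surface is not None
        and dej is not None
        and muscle is not None
        and surface < dej < muscle
    )
    return BoundaryProfile(surface, dej, muscle, valid)


def segment_volume(
    averaged: Sequence[AveragedBScan], cal: CalibrationReference
) -> tuple[np.ndarray, list[BoundaryProfile]]:
    """Segment every usable averaged A-scan of a volume.

    Returns the stacked columns (axial, n_columns_total) and one
    :class:`BoundaryProfile` per column.
    """
    columns = np.concatenate([b.intensity for b in averaged], axis=1)
    profiles = [segment_column(columns[:, j], cal) for j in range(columns.shape[1])]
    return columns, profiles


def measure_thickness(
    profiles: Sequence[BoundaryProfile],
    axial_pitch: float,
    refractive_index: float = 1.0,
) -> ThicknessResult:
    """Skin thickness per valid column: (muscle_idx - surface_idx) times the
    axial pitch, optionally divided by a refractive index (default 1.0, i.e.
    optical path reported as-is)."""
    if refractive_index <= 0:
        raise ValidationError("refractive index must be positive")
    vals = [
        (p.muscle_idx - p.surface_idx) * axial_pitch / refractive_index
        for p in profiles
        if p.valid
    ]
    if not vals:
        raise SegmentationError(
            "no valid columns: layer segmentation failed for the whole volume"
        )
    per_ascan = np.asarray(vals, dtype=float)
    return ThicknessResult(
        per_ascan=per_ascan,
        volume_mean=float(per_ascan.mean()),
        n_valid=per_ascan.size,
        n_total=len(profiles),
    )
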