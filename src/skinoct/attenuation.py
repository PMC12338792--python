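"""Attenuation-coefficient estimation by linear fit of log intensity with
depth over the dermal region of interest.

Under the single-scattering model the mean detected signal decays as
``I(z) = I0 * exp(-mu * z)``, so on a logarithmic intensity scale the depth
profile is a straight line with slope proportional to ``-mu``. Each valid
averaged A-scan is fit by ordinary least squares from just below the DEJ
peak to the detected dermis-muscle boundary; the per-column coefficients
are averaged into a per-volume value. No round-trip factor is applied: the
reported mu is the single-pass decay rate (a config flag can halve it for
comparison with round-trip-corrected literature).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import SegmentationError, ValidationError
from .segmentation import BoundaryProfile

#: Conversion from -slope (per mm of depth, in stored log units) to mu in
#: mm^-1 for each supported intensity scale.
_SCALE_FACTOR = {
    "log": 1.0,               # natural-log intensity: slope = -mu
    "db": np.log(10.0) / 10.0,  # 10*log10 intensity
}

#: Points excluded at the shallow/deep ends of the ROI so the specular DEJ
#: spike and partial-volume pixels at the detected muscle boundary never
#: contaminate the Lambert-Beer line.
DEFAULT_ROI_TRIM_START = 2
DEFAULT_ROI_TRIM_END = 1


@dataclass
class AttenuationFit:
    """OLS fit of one averaged A-scan over [roi_start, roi_end)."""

    mu: float
    intercept: float
    roi_start: int
    roi_end: int
    n_points: int
    residual_rms: float
    valid: bool


@dataclass
class AttenuationResult:
    """Per-volume attenuation: valid per-column mu values (mm^-1), their
    mean, and QC counts."""

    per_ascan: np.ndarray
    volume_mean: float
    n_valid: int
    n_total: int


def fit_attenuation(
    column: np.ndarray,
    profile: BoundaryProfile,
    axial_pitch: float,
    scale: str = "log",
    min_points: int = 5,
    roi_trim_start: int = DEFAULT_ROI_TRIM_START,
    roi_trim_end: int = DEFAULT_ROI_TRIM_END,
    round_trip: bool = False,
) -> AttenuationFit:
    """Fit ``mu`` (mm^-1) over the dermal ROI of one column.

    The ROI runs from ``dej_idx + roi_trim_start`` to
    ``muscle_idx - roi_trim_end`` (exclusive). A ROI shorter than
    ``min_points`` yields an invalid fit, not an exception.
    """
    if scale not in _SCALE_FACTOR:
        raise ValidationError(f"unknown intensity scale {scale!r}")
    if not profile.valid:
        return AttenuationFit(np.nan, np.nan, -1, -1, 0, np.nan, False)
    column = np.asarray(column, dtype=float)
    start = profile.dej_idx + roi_trim_start
    end = profile.muscle_idx - roi_trim_end
    n = end - start
    if n < max(min_points, 2):
        return AttenuationFit(np.nan, np.nan, start, end, max(n, 0), np.nan, False)
    z_mm = np.arange(start, end) * axial_pitch * 1e-3
    y = column[start:end]
    slope, intercept = np.polyfit(z_mm, y, 1)
    mu = -slope * _SCALE_FACTOR[scale]
    if round_trip:
        mu /= 2.0
    resid = y - (slope * z_mm + intercept)
    return AttenuationFit(
        mu=float(mu),
        intercept=float(intercept),
        roi_start=start,
        roi_end=end,
        n_points=n,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        valid=True,
    )


def measure_attenuation(
    columns: np.ndarray,
    profiles: Sequence[BoundaryProfile],
    axial_pitch: float,
    scale: str = "log",
    **fit_kwargs,
) -> AttenuationResult:
    """Fit every usable averaged A-scan and average the valid coefficients.

    ``columns`` is the (axial, n_columns) stack aligned with ``profiles``.
    Raises :class:`SegmentationError` when no column yields a valid fit.
    """
    fits = [
        fit_attenuation(columns[:, j], p, axial_pitch, scale, **fit_kwargs)
        for j, p in enumerate(profiles)
    ]
    mus = np.asarray([f.mu for f in fits if f.valid], dtype=float)
    if mus.size == 0:
        raise SegmentationError("no valid attenuation fits in this volume")
    return AttenuationResult(
        per_ascan=mus,
        volume_mean=float(mus.mean()),
        n_valid=mus.size,
        n_total=len(profiles),
    )
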