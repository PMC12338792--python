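"""Reading and writing OCT volumes, region annotations, and study tables.

Volumes are stored as multi-page TIFF (one page per B-scan) with a JSON
sidecar carrying pixel pitches, the logarithmic intensity convention and
provenance; annotations are JSON; the study design table is CSV. Indexing is
0-based with half-open ranges, axial index 0 being the shallowest pixel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError, ValidationError

#: Logarithmic intensity conventions understood by the attenuation fit.
#: "log" is natural-log intensity (slope of the depth profile is -mu);
#: "db" is 10*log10 intensity.
SCALES = ("log", "db")

GROUPS = ("control", "uvr_control", "uvr_nmn", "uvr_pl")
SITES = ("back", "side", "stomach")
REGIONS = ("air", "muscle")
MONTHS = tuple(range(8))

_STUDY_FIELDS = ("mouse_id", "group", "site", "month", "volume_path")


@dataclass
class OctVolume:
    """A 3-D log-scale OCT intensity volume.

    ``intensity`` is indexed ``(axial pixel, lateral A-scan, B-scan)``.
    Pitches are in micrometres. ``scale`` names the logarithmic intensity
    convention (see :data:`SCALES`).
    """

    intensity: np.ndarray
    axial_pitch: float
    lateral_pitch: float
    scale: str = "log"
    source_id: str = ""

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity)
        if self.intensity.ndim != 3 or min(self.intensity.shape) < 1:
            raise ValidationError(
                f"intensity must be a 3-D array with all dimensions >= 1, "
                f"got shape {self.intensity.shape}"
            )
        if not (self.axial_pitch > 0 and self.lateral_pitch > 0):
            raise ValidationError("pixel pitches must be positive")
        if self.scale not in SCALES:
            raise ValidationError(f"scale must be one of {SCALES}, got {self.scale!r}")
        if not np.all(np.isfinite(self.intensity)):
            raise ValidationError("intensity values must be finite")

    @property
    def n_axial(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_ascans_per_bscan(self) -> int:
        return self.intensity.shape[1]

    @property
    def n_bscans(self) -> int:
        return self.intensity.shape[2]


@dataclass(frozen=True)
class RegionAnnotation:
    """A rectangular air or muscle reference region, half-open index ranges."""

    volume_id: str
    region: str
    axial: tuple[int, int]
    lateral: tuple[int, int]
    bscan: tuple[int, int]

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValidationError(
                f"region must be one of {REGIONS}, got {self.region!r}"
            )
        for name, (lo, hi) in (
            ("axial", self.axial),
            ("lateral", self.lateral),
            ("bscan", self.bscan),
        ):
            if not (0 <= lo < hi):
                raise ValidationError(
                    f"{name} bounds must satisfy 0 <= lo < hi, got ({lo}, {hi})"
                )


def extract_region(volume: OctVolume, ann: RegionAnnotation) -> np.ndarray:
    """Voxels of ``volume`` inside the annotated box.

    Raises :class:`ValidationError` if the box exceeds the volume shape.
    """
    shape = volume.intensity.shape
    for (lo, hi), dim, name in zip(
        (ann.axial, ann.lateral, ann.bscan), shape, ("axial", "lateral", "bscan")
    ):
        if hi > dim:
            raise ValidationError(
                f"{name} bounds ({lo}, {hi}) exceed volume extent {dim}"
            )
    return volume.intensity[
        ann.axial[0] : ann.axial[1],
        ann.lateral[0] : ann.lateral[1],
        ann.bscan[0] : ann.bscan[1],
    ]


@dataclass(frozen=True)
class StudyRecord:
    """One imaging session: which mouse, group, site and month, and where
    the corresponding volume lives on disk."""

    mouse_id: str
    group: str
    site: str
    month: int
    volume_path: str

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(
                f"unknown group {self.group!r}; allowed values: {GROUPS}"
            )
        if self.site not in SITES:
            raise ValidationError(
                f"unknown site {self.site!r}; allowed values: {SITES}"
            )
        if self.month not in MONTHS:
            raise ValidationError(
                f"month must be an integer in {MONTHS[0]}..{MONTHS[-1]}, "
                f"got {self.month!r}"
            )


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_volume(volume: OctVolume, path: str | Path) -> Path:
    """Write a volume as a multi-page TIFF (one page per B-scan) plus a JSON
    sidecar with pitches, scale convention and provenance."""
    path = Path(path)
    # pages = B-scans: (bscan, axial, lateral)
    pages = np.ascontiguousarray(np.moveaxis(volume.intensity, 2, 0))
    tifffile.imwrite(path, pages, photometric="minisblack")
    meta = {
        "axial_pitch": volume.axial_pitch,
        "lateral_pitch": volume.lateral_pitch,
        "scale": volume.scale,
        "source_id": volume.source_id,
        "shape": list(volume.intensity.shape),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_volume(path: str | Path) -> OctVolume:
    """Read a multi-page TIFF volume with its JSON sidecar.

    Missing sidecar fields and TIFF/sidecar shape mismatches raise
    :class:`FormatError` rather than falling back to defaults.
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"missing JSON sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in ("axial_pitch", "lateral_pitch", "scale", "shape"):
        if key not in meta:
            raise FormatError(f"sidecar {sidecar} missing required field {key!r}")
    pages = tifffile.imread(path)
    if pages.ndim == 2:  # single B-scan collapses to 2-D
        pages = pages[None]
    intensity = np.moveaxis(pages, 0, 2)
    if list(intensity.shape) != list(meta["shape"]):
        raise FormatError(
            f"TIFF shape {list(intensity.shape)} does not match sidecar "
            f"shape {meta['shape']}"
        )
    return OctVolume(
        intensity=intensity,
        axial_pitch=float(meta["axial_pitch"]),
        lateral_pitch=float(meta["lateral_pitch"]),
        scale=str(meta["scale"]),
        source_id=str(meta.get("source_id", "")),
    )


def write_annotations(annotations: Sequence[RegionAnnotation], path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps([asdict(a) for a in annotations], indent=1))
    return path


def read_annotations(path: str | Path) -> list[RegionAnnotation]:
    raw = json.loads(Path(path).read_text())
    return [
        RegionAnnotation(
            volume_id=d["volume_id"],
            region=d["region"],
            axial=tuple(d["axial"]),
            lateral=tuple(d["lateral"]),
            bscan=tuple(d["bscan"]),
        )
        for d in raw
    ]


def write_study_table(records: Sequence[StudyRecord], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame([asdict(r) for r in records], columns=list(_STUDY_FIELDS))
    df.to_csv(path, index=False)
    return path


def read_study_table(path: str | Path) -> list[StudyRecord]:
    """Read and validate the study design table (CSV).

    Rows are validated against the closed group/site vocabularies; duplicate
    (mouse, site, month) combinations are rejected.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [f for f in _STUDY_FIELDS if f not in df.columns]
    if missing:
        raise FormatError(f"study table missing columns: {missing}")
    records = []
    for _, row in df.iterrows():
        try:
            month = int(row["month"])
        except (TypeError, ValueError):
            raise ValidationError(f"month {row['month']!r} is not an integer")
        records.append(
            StudyRecord(
                mouse_id=str(row["mouse_id"]),
                group=str(row["group"]),
                site=str(row["site"]),
                month=month,
                volume_path=str(row["volume_path"]),
            )
        )
    seen: set[tuple[str, str, int]] = set()
    for rec in records:
        key = (rec.mouse_id, rec.site, rec.month)
        if key in seen:
            raise ValidationError(
                f"duplicate study record for mouse={rec.mouse_id} "
                f"site={rec.site} month={rec.month}"
            )
        seen.add(key)
    return records
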