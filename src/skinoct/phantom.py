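"""Synthetic four-layer skin phantom OCT volumes with known ground truth.

The phantom stacks air, epidermis, dermis and muscle. Within each layer the
noiseless linear signal is ``A0 * exp(-mu * (z - z_top))`` with ``A0`` the
layer reflectivity and ``mu`` its attenuation in mm^-1 — the same
single-scattering Lambert-Beer form the downstream fit inverts. The skin
surface and the dermal-epidermal junction (DEJ) are rendered as specular
reflections — additive amplitude spikes distributed over the two pixels
bracketing the interface by sub-pixel weight — so that peak detection sees
a distinct first and second peak even after lateral block averaging of
jittered columns. The dermis-muscle interface is a plain amplitude step,
matching how that boundary is found (a threshold crossing, not a peak).

Speckle is multiplicative gamma noise with unit mean applied to the linear
amplitude before the log transform, so averaging linear amplitude over many
A-scans converges to the noiseless signal and the exponential-decay fit is
unbiased in the mean. Volumes are stored as natural-log intensity
(``scale="log"``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ValidationError
from .io import OctVolume

LAYER_ORDER = ("air", "epidermis", "dermis", "muscle")

#: Noise-floor linear amplitude of the air region (log ~ -23).
AIR_AMPLITUDE = 1e-10
#: Muscle plateau linear amplitude (log = -20), below the dimmest dermis
#: bottom produced by the attenuation range the phantom is used over.
MUSCLE_AMPLITUDE = float(np.exp(-20.0))

#: Jitter fields are clipped at this many standard deviations so interface
#: ordering is preserved exactly and realized depths stay within 4 sigma of
#: nominal.
_JITTER_CLIP = 3.5


@dataclass(frozen=True)
class LayerSpec:
    """One layer of the phantom.

    thickness is in micrometres (for air: the standoff above the surface),
    reflectivity is the linear backscatter amplitude at the layer top, and
    attenuation is the exponential decay rate within the layer in mm^-1.
    """

    name: str
    thickness: float
    reflectivity: float
    attenuation: float

    def __post_init__(self) -> None:
        if self.name not in LAYER_ORDER:
            raise ValidationError(f"unknown layer name {self.name!r}")
        if not self.thickness > 0:
            raise ValidationError(f"{self.name}: thickness must be > 0")
        if self.reflectivity < 0 or self.attenuation < 0:
            raise ValidationError(
                f"{self.name}: reflectivity and attenuation must be >= 0"
            )
        if self.name == "air" and self.attenuation != 0:
            raise ValidationError("air layer must have zero attenuation")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, optics and noise of a synthetic volume.

    ``speckle_shape`` is the gamma shape parameter of the multiplicative
    speckle (larger = smoother); ``None`` disables speckle entirely.
    ``thickness_jitter`` is the standard deviation (um) of a smooth lateral
    corrugation shifting all interfaces together. ``n_axial`` is the axial
    window in pixels.
    """

    layers: tuple[LayerSpec, LayerSpec, LayerSpec, LayerSpec]
    axial_pitch: float = 4.0
    n_axial: int = 256
    n_ascans_per_bscan: int = 1355
    n_bscans: int = 120
    lateral_pitch: float = 4.4
    speckle_shape: float | None = 10.0
    thickness_jitter: float = 6.0
    seed: int = 0
    spike_multiplier: float = 2.0

    def __post_init__(self) -> None:
        names = tuple(layer.name for layer in self.layers)
        if names != LAYER_ORDER:
            raise ValidationError(
                f"layer order must be exactly {LAYER_ORDER}, got {names}"
            )
        if self.n_ascans_per_bscan < 1 or self.n_bscans < 1 or self.n_axial < 2:
            raise ValidationError("lateral counts must be >= 1 and n_axial >= 2")
        if not (self.axial_pitch > 0 and self.lateral_pitch > 0):
            raise ValidationError("pixel pitches must be positive")
        if self.speckle_shape is not None and not self.speckle_shape > 0:
            raise ValidationError("speckle_shape must be positive or None")
        if self.thickness_jitter < 0:
            raise ValidationError("thickness_jitter must be >= 0")

    @property
    def window_depth(self) -> float:
        """Axial window depth in micrometres."""
        return self.n_axial * self.axial_pitch

    @property
    def nominal_interfaces(self) -> tuple[float, float, float]:
        """Nominal (surface, DEJ, muscle) interface depths in micrometres."""
        air, epi, der, _ = self.layers
        surface = air.thickness
        return (surface, surface + epi.thickness, surface + epi.thickness + der.thickness)


@dataclass
class GroundTruth:
    """Realized per-lateral-position interface depths (um) and the dermal
    attenuation (mm^-1); skin thickness is muscle depth minus surface depth."""

    surface_depth: np.ndarray
    dej_depth: np.ndarray
    muscle_depth: np.ndarray
    dermal_attenuation: float

    def __post_init__(self) -> None:
        if not (
            np.all(self.surface_depth < self.dej_depth)
            and np.all(self.dej_depth < self.muscle_depth)
        ):
            raise ValidationError("interfaces must satisfy surface < DEJ < muscle")

    @property
    def skin_thickness(self) -> np.ndarray:
        return self.muscle_depth - self.surface_depth

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps(
                {
                    "surface_depth": self.surface_depth.tolist(),
                    "dej_depth": self.dej_depth.tolist(),
                    "muscle_depth": self.muscle_depth.tolist(),
                    "dermal_attenuation": self.dermal_attenuation,
                },
            )
        )
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            surface_depth=np.asarray(d["surface_depth"], dtype=float),
            dej_depth=np.asarray(d["dej_depth"], dtype=float),
            muscle_depth=np.asarray(d["muscle_depth"], dtype=float),
            dermal_attenuation=float(d["dermal_attenuation"]),
        )


def default_phantom(
    dermal_attenuation: float = 40.0,
    dermis_thickness: float = 400.0,
    **overrides,
) -> PhantomSpec:
    """The default four-layer phantom.

    Air standoff 100 um, epidermis 20 um at 40 mm^-1, dermis 400 um at the
    requested attenuation (40 mm^-1 baseline-like, 25 mm^-1 UVR-like), and a
    non-attenuating muscle plateau sized to fill the rest of the axial
    window. Geometry defaults mirror the instrument raster (1355 A-scans x
    120 B-scans).
    """
    window = overrides.get("n_axial", 256) * overrides.get("axial_pitch", 4.0)
    muscle_thickness = window - (100.0 + 20.0 + dermis_thickness)
    if muscle_thickness < 40.0:
        raise ValidationError(
            "dermis too thick for the axial window: muscle layer would be "
            f"{muscle_thickness:.0f} um (< 40 um)"
        )
    layers = (
        LayerSpec("air", 100.0, AIR_AMPLITUDE, 0.0),
        LayerSpec("epidermis", 20.0, 1.0, 40.0),
        LayerSpec("dermis", dermis_thickness, 1.0, dermal_attenuation),
        LayerSpec("muscle", muscle_thickness, MUSCLE_AMPLITUDE, 0.0),
    )
    return PhantomSpec(layers=layers, **overrides)


def _noiseless_bscan(
    spec: PhantomSpec,
    surface: np.ndarray,
    dej: np.ndarray,
    muscle: np.ndarray,
) -> np.ndarray:
    """Noiseless linear amplitude, shape (n_axial, n_columns)."""
    air, epi, der, mus = spec.layers
    z = (np.arange(spec.n_axial) * spec.axial_pitch)[:, None]  # um
    surface = np.atleast_1d(np.asarray(surface, dtype=float))[None, :]
    dej = np.atleast_1d(np.asarray(dej, dtype=float))[None, :]
    muscle = np.atleast_1d(np.asarray(muscle, dtype=float))[None, :]
    muscle_bottom = muscle + mus.thickness

    amp = np.full((spec.n_axial, surface.shape[1]), air.reflectivity, dtype=float)
    mm = 1e-3  # um -> mm for the attenuation exponent
    in_epi = (z >= surface) & (z < dej)
    in_der = (z >= dej) & (z < muscle)
    in_mus = (z >= muscle) & (z < muscle_bottom)
    amp = np.where(in_epi, epi.reflectivity * np.exp(-epi.attenuation * mm * (z - surface)), amp)
    amp = np.where(in_der, der.reflectivity * np.exp(-der.attenuation * mm * (z - dej)), amp)
    amp = np.where(in_mus, mus.reflectivity * np.exp(-mus.attenuation * mm * (z - muscle)), amp)

    # Additive specular spikes at the surface and DEJ interfaces, energy
    # split between the two bracketing pixels by sub-pixel position so the
    # spike survives block averaging under lateral jitter.
    cols = np.arange(surface.shape[1])
    for depth, refl in (
        (surface[0], epi.reflectivity),
        (dej[0], der.reflectivity),
    ):
        pos = depth / spec.axial_pitch
        lo = np.floor(pos).astype(int)
        hi = np.minimum(lo + 1, spec.n_axial - 1)
        w_hi = pos - lo
        spike = spec.spike_multiplier * refl
        amp[lo, cols] += (1.0 - w_hi) * spike
        amp[hi, cols] += w_hi * spike
    return amp


def _apply_speckle(amp: np.ndarray, shape: float | None, rng: np.random.Generator) -> np.ndarray:
    if shape is None:
        return amp
    return amp * rng.gamma(shape, 1.0 / shape, size=amp.shape)


def generate_ascan(
    spec: PhantomSpec,
    interface_depths: tuple[float, float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """One log-intensity A-scan for the given (surface, DEJ, muscle) depths.

    Interface depths must be strictly increasing and lie inside the axial
    window; a violation raises :class:`ValidationError` naming the offending
    interface.
    """
    surface, dej, muscle = interface_depths
    names = ("surface (air/epidermis)", "DEJ (epidermis/dermis)", "dermis/muscle")
    prev = 0.0
    for depth, name in zip((surface, dej, muscle), names):
        if not (prev < depth < spec.window_depth):
            raise ValidationError(
                f"{name} interface at {depth} um is outside the valid range "
                f"({prev}, {spec.window_depth}) um"
            )
        prev = depth
    amp = _noiseless_bscan(spec, [surface], [dej], [muscle])[:, 0]
    amp = _apply_speckle(amp, spec.speckle_shape, rng)
    return np.log(amp)


def _jitter_field(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Smooth lateral corrugation (um), shape (n_ascans, n_bscans)."""
    shape = (spec.n_ascans_per_bscan, spec.n_bscans)
    if spec.thickness_jitter == 0:
        return np.zeros(shape)
    field = rng.standard_normal(shape)
    # correlation length ~ 20 A-scans laterally, ~ 4 B-scans across.
    field = gaussian_filter(field, sigma=(20.0, 4.0), mode="reflect")
    sd = field.std()
    if sd > 0:
        field *= spec.thickness_jitter / sd
    return np.clip(
        field, -_JITTER_CLIP * spec.thickness_jitter, _JITTER_CLIP * spec.thickness_jitter
    )


def generate_volume(spec: PhantomSpec) -> tuple[OctVolume, GroundTruth]:
    """Generate a speckled (or noiseless) phantom volume with ground truth.

    A single RNG stream seeded from ``spec.seed`` drives the jitter field and
    the speckle, so volumes are bit-reproducible. The realized per-position
    interface depths (including jitter) are returned as :class:`GroundTruth`.
    """
    total = sum(layer.thickness for layer in spec.layers)
    if total > spec.window_depth:
        raise ValidationError(
            f"total layer stack ({total} um) is deeper than the axial window "
            f"({spec.window_depth} um)"
        )
    s0, d0, m0 = spec.nominal_interfaces
    margin = _JITTER_CLIP * spec.thickness_jitter
    if s0 - margin <= 0 or m0 + margin >= spec.window_depth:
        raise ValidationError(
            "jitter could push interfaces outside the axial window; reduce "
            "thickness_jitter or enlarge the air standoff / axial window"
        )

    rng = np.random.default_rng(spec.seed)
    shift = _jitter_field(spec, rng)
    surface, dej, muscle = s0 + shift, d0 + shift, m0 + shift

    intensity = np.empty(
        (spec.n_axial, spec.n_ascans_per_bscan, spec.n_bscans), dtype=np.float32
    )
    for b in range(spec.n_bscans):
        amp = _noiseless_bscan(spec, surface[:, b], dej[:, b], muscle[:, b])
        amp = _apply_speckle(amp, spec.speckle_shape, rng)
        intensity[:, :, b] = np.log(amp)

    volume = OctVolume(
        intensity=intensity,
        axial_pitch=spec.axial_pitch,
        lateral_pitch=spec.lateral_pitch,
        scale="log",
        source_id=f"phantom(seed={spec.seed})",
    )
    truth = GroundTruth(
        surface_depth=surface,
        dej_depth=dej,
        muscle_depth=muscle,
        dermal_attenuation=spec.layers[2].attenuation,
    )
    return volume, truth


def reference_annotations(
    spec: PhantomSpec, volume_id: str
) -> "list":  # -> list[RegionAnnotation]
    """Air and muscle calibration annotations for a flat (jitter-free)
    phantom built from ``spec``.

    The air box sits above the surface; the muscle box starts one pixel above
    the nominal dermis-muscle interface, the way an annotator outlining from
    the visible bright boundary would, which places the pooled muscle mean
    slightly above the muscle plateau so the boundary-crossing rule fires at
    the interface itself.
    """
    from .io import RegionAnnotation

    s0, _, m0 = spec.nominal_interfaces
    s_px = int(round(s0 / spec.axial_pitch))
    m_px = int(round(m0 / spec.axial_pitch))
    air_hi = max(2, s_px - 5)
    muscle_lo, muscle_hi = m_px - 1, min(m_px + 4, spec.n_axial)
    lat = (0, spec.n_ascans_per_bscan)
    bsc = (0, spec.n_bscans)
    return [
        RegionAnnotation(volume_id, "air", (1, air_hi), lat, bsc),
        RegionAnnotation(volume_id, "muscle", (muscle_lo, muscle_hi), lat, bsc),
    ]
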