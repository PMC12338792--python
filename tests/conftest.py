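import numpy as np
import pytest

import skinoct as sk

# Reduced lateral geometry keeps unit tests fast; the axial window and layer
# stack are the full defaults so thresholds behave as in a full-size volume.
SMALL = dict(n_ascans_per_bscan=300, n_bscans=6)


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Flat, speckle-free phantom at 30 mm^-1 with its calibration."""
    spec = sk.default_phantom(
        30.0, speckle_shape=None, thickness_jitter=0.0, seed=11, **SMALL
    )
    vol, truth = sk.generate_volume(spec)
    cal = sk.calibrate(
        [(vol, sk.reference_annotations(spec, "self"))], prominence_value=0.9
    )
    return spec, vol, truth, cal


@pytest.fixture(scope="session")
def speckled_calibration():
    """Calibration from a flat, speckled baseline-like reference phantom."""
    spec = sk.default_phantom(40.0, thickness_jitter=0.0, seed=99, **SMALL)
    vol, _ = sk.generate_volume(spec)
    return sk.calibrate([(vol, sk.reference_annotations(spec, "ref"))])


@pytest.fixture(scope="session")
def speckled_phantom(speckled_calibration):
    """Default-speckle phantom at 25 mm^-1 plus the shared calibration."""
    spec = sk.default_phantom(25.0, seed=5, **SMALL)
    vol, truth = sk.generate_volume(spec)
    return spec, vol, truth, speckled_calibration


def analyze(vol, cal, window=10, trim=15, **fit_kwargs):
    """Segment + measure a volume; convenience used across test modules."""
    averaged = sk.average_volume(vol, window, trim)
    columns, profiles = sk.segment_volume(averaged, cal)
    thickness = sk.measure_thickness(profiles, vol.axial_pitch)
    atten = sk.measure_attenuation(
        columns, profiles, vol.axial_pitch, vol.scale, **fit_kwargs
    )
    return thickness, atten, profiles


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
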