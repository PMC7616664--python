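import numpy as np
import pytest

from nanohisto import histoquant, synthgen


@pytest.fixture(scope="session")
def ct26_field():
    """CT26-calibrated field (89 vessels, 7.7% TAM AF) with ground truth."""
    return synthgen.make_tissue_image(synthgen.BUILTIN_PROFILES["CT26"], 1)


@pytest.fixture(scope="session")
def a431_field():
    """A431-calibrated field (28 vessels, 91.3% perfused, 2.2% TAM AF)."""
    return synthgen.make_tissue_image(synthgen.BUILTIN_PROFILES["A431"], 1)


@pytest.fixture
def tiny_profile():
    """Small, quick-to-render profile for structural tests."""
    return synthgen.TissueProfile(
        name="tiny", n_vessels=12,
        costain_fractions={"lectin": 0.5, "aSMA": 0.25},
        tam_area_fraction=0.04, lymph_vessel_count=4, nuclear_density=40,
        field_size_px=(160, 160),
    )


def disk_image(shape=(64, 64), centers=((32, 32),), radius=5, value=1.0):
    """Single-channel test image with filled disks on a zero background."""
    from skimage import draw

    arr = np.zeros(shape)
    for (r, c) in centers:
        rr, cc = draw.disk((r, c), radius, shape=shape)
        arr[rr, cc] = value
    return arr


@pytest.fixture
def make_image():
    """Factory wrapping raw channel arrays into a StainedTissueImage."""

    def _make(**channels):
        return histoquant.StainedTissueImage(channels=channels)

    return _make
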