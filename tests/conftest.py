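import numpy as np
import pytest

from aframan import calibration, phantom


@pytest.fixture(scope="session")
def demo_map() -> phantom.TissueMap:
    """Small specimen: adipose field, stroma halo, central tumour."""
    return phantom.demo_tissue_map(shape=(120, 120), tumour_radius_px=22.0,
                                   stroma_halo_px=12.0, seed=11)


@pytest.fixture(scope="session")
def refs():
    return calibration.default_refs()


@pytest.fixture(scope="session")
def instrument() -> phantom.InstrumentModel:
    return phantom.InstrumentModel()


@pytest.fixture(scope="session")
def measured_standards(refs, instrument):
    """As-acquired calibration standards seen through the instrument."""
    std = instrument.distort(calibration.render_intensity_standard(refs))
    ps = instrument.distort(calibration.render_polystyrene())
    return std, ps


def quiet_models(**overrides):
    """Band models with noise, baseline and cosmic rays switched off."""
    kwargs = dict(noise_sd=0.0, cosmic_ray_rate=0.0, baseline_fraction=0.0)
    kwargs.update(overrides)
    return phantom.default_band_models(**kwargs)


@pytest.fixture(scope="session")
def class_points(demo_map):
    """One in-specimen point per tissue class present in the demo map."""
    pts = {}
    for cls in ("adipose", "stroma", "tumour"):
        code = phantom.Tissue[cls.upper()]
        coords = np.argwhere(demo_map.labels == code)
        pts[cls] = tuple(coords[len(coords) // 2])
    return pts
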