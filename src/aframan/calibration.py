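"""Built-in calibration references and their CSV interchange.

The polystyrene shift table follows the ASTM E1840 convention for the
fingerprint region.  The relative-intensity response curve shipped here is
a smooth synthetic stand-in with the qualitative shape of a certified
NIST-style fluorescence standard at 785 nm excitation; laboratories with a
real certificate supply their own curve via CSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .profiles import RAMAN_GRID_CM1
from .ramanproc import CalibrationRefs, RamanSpectrum

#: ASTM E1840 polystyrene Raman shifts within 600-1800 cm^-1.
POLYSTYRENE_PEAKS_CM1 = (620.9, 795.8, 1001.4, 1031.8, 1155.3, 1450.5, 1583.1, 1602.3)


def synthetic_certified_response(
    wavenumber: np.ndarray | None = None,
) -> np.ndarray:
    """Smooth synthetic certified-emission curve (relative units, peak 1).

    A broad skewed hump peaking in the middle of the fingerprint region;
    strictly positive everywhere, as a certified curve must be.
    """
    wn = RAMAN_GRID_CM1 if wavenumber is None else np.asarray(wavenumber, float)
    x = (wn - 600.0) / 1200.0
    y = np.exp(-0.5 * ((x - 0.45) / 0.35) ** 2) * (1.0 + 0.25 * x)
    return y / y.max()


def default_refs(wavenumber: np.ndarray | None = None) -> CalibrationRefs:
    wn = RAMAN_GRID_CM1 if wavenumber is None else np.asarray(wavenumber, float)
    return CalibrationRefs(
        polystyrene_peaks_cm1=np.array(POLYSTYRENE_PEAKS_CM1),
        response_wavenumber=wn,
        response_intensity=synthetic_certified_response(wn),
    )


def render_polystyrene(
    wavenumber: np.ndarray | None = None,
    peak_sigma_cm1: float = 4.0,
    count_scale: float = 2000.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> RamanSpectrum:
    """Synthetic measured polystyrene spectrum with peaks at the reference shifts."""
    wn = RAMAN_GRID_CM1 if wavenumber is None else np.asarray(wavenumber, float)
    amps = (0.6, 0.4, 1.0, 0.5, 0.3, 0.35, 0.45, 0.7)
    y = np.zeros_like(wn)
    for center, amp in zip(POLYSTYRENE_PEAKS_CM1, amps):
        y += amp * np.exp(-0.5 * ((wn - center) / peak_sigma_cm1) ** 2)
    y *= count_scale
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, wn.size)
    return RamanSpectrum(wavenumber=wn, counts=y, meta={"standard": "polystyrene"})


def render_intensity_standard(
    refs: CalibrationRefs,
    wavenumber: np.ndarray | None = None,
    count_scale: float = 30000.0,
) -> RamanSpectrum:
    """Noiseless 'measured' intensity standard equal to the certified curve."""
    wn = RAMAN_GRID_CM1 if wavenumber is None else np.asarray(wavenumber, float)
    return RamanSpectrum(
        wavenumber=wn,
        counts=refs.response_on(wn) * count_scale,
        meta={"standard": "intensity"},
    )


def write_refs(refs: CalibrationRefs, polystyrene_csv: Path, response_csv: Path) -> None:
    pd.DataFrame({"peak_cm-1": refs.polystyrene_peaks_cm1}).to_csv(
        polystyrene_csv, index=False
    )
    pd.DataFrame(
        {
            "wavenumber_cm-1": refs.response_wavenumber,
            "relative_intensity": refs.response_intensity,
        }
    ).to_csv(response_csv, index=False)


def read_refs(polystyrene_csv: Path, response_csv: Path) -> CalibrationRefs:
    peaks = pd.read_csv(polystyrene_csv)["peak_cm-1"].to_numpy()
    resp = pd.read_csv(response_csv)
    return CalibrationRefs(
        polystyrene_peaks_cm1=np.sort(peaks),
        response_wavenumber=resp["wavenumber_cm-1"].to_numpy(),
        response_intensity=resp["relative_intensity"].to_numpy(),
    )
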