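"""Versioned spectral model tables for the synthetic specimen generator.

The tables below define the per-tissue-class autofluorescence emission
mixtures (365 nm excitation) and Raman band models used by
:mod:`aframan.phantom`.  Component positions follow the published peak
structure for breast tissue: adipose emission is dominated by a 475/500 nm
pair with smaller lipopigment/porphyrin features at 550 and 595 nm, while
stroma and tumour share a broad NAD(P)H-like band near 460 nm that is not
usefully distinguishable between the two classes.

Amplitudes and widths are calibration constants, fixed once so that the
band-integral ratio Filter 1 (442-488 nm) / Filter 2 (480-562 nm) of each
class lands in its screening band: adipose in 0.2-0.8, stroma/tumour in
0.8-2, and fibrosis just below 1.  They are versioned rather than
hard-coded at call sites; bump ``EMISSION_TABLE_VERSION`` when retuning.
"""

from __future__ import annotations

import numpy as np

EMISSION_TABLE_VERSION = "1.0"

#: 1-nm emission wavelength grid (nm) covering both detection filters.
WAVELENGTH_GRID_NM = np.arange(400.0, 701.0, 1.0)

#: Gaussian emission components per tissue class: (center nm, sigma nm, amplitude).
EMISSION_COMPONENTS: dict[str, list[tuple[float, float, float]]] = {
    "adipose": [
        (475.0, 9.0, 1.00),   # vitamin-associated pair
        (500.0, 9.0, 0.80),
        (550.0, 13.0, 0.40),  # lipopigments (ceroid/lipofuscin)
        (595.0, 13.0, 0.22),  # porphyrin
    ],
    "stroma": [
        (460.0, 38.0, 1.00),  # NADH/NADPH
    ],
    # Near-identical to stroma by design: the two classes are not separable
    # in 365 nm excited emission, only adipose is.
    "tumour": [
        (460.0, 37.0, 1.00),
    ],
    # Stroma-like, with extra long-wavelength emission pulling the filter
    # ratio just below 1 so that fibrosis-heavy specimens can be excluded
    # by restricting the retained band to 1-2.
    "fibrosis": [
        (460.0, 38.0, 1.00),
        (520.0, 30.0, 0.35),
    ],
}

RAMAN_TABLE_VERSION = "1.0"

#: 1 cm^-1 canonical Raman shift grid (fingerprint region).
RAMAN_GRID_CM1 = np.arange(600.0, 1801.0, 1.0)

#: Raman bands per tissue class: (center cm^-1, sigma cm^-1, relative amplitude).
#: Adipose is lipid-dominated (CH2 deformation at 1441 cm^-1 strongest, C=C at
#: 1655, =CH pair at 1260/1275, skeletal/PO2 complex at 1080-1095); stroma is
#: collagen-rich (860/938 cm^-1 prolines plus phenylalanine 1004); tumour has
#: the phenylalanine 1004 cm^-1 band dominant over weak collagen.
RAMAN_BANDS: dict[str, list[tuple[float, float, float]]] = {
    "adipose": [
        (1078.0, 8.0, 0.20),
        (1094.0, 8.0, 0.20),
        (1260.0, 7.0, 0.26),
        (1275.0, 7.0, 0.26),
        (1301.0, 9.0, 0.30),
        (1441.0, 10.0, 1.00),
        (1655.0, 11.0, 0.55),
        (1745.0, 8.0, 0.15),
    ],
    "stroma": [
        (860.0, 9.0, 0.60),
        (938.0, 9.0, 0.58),
        (1004.0, 5.0, 0.42),
        (1245.0, 11.0, 0.38),
        (1270.0, 10.0, 0.32),
        (1450.0, 10.0, 0.55),
        (1655.0, 12.0, 0.72),
    ],
    "tumour": [
        (860.0, 9.0, 0.22),
        (938.0, 9.0, 0.20),
        (1004.0, 5.0, 0.80),
        (1090.0, 9.0, 0.25),
        (1245.0, 11.0, 0.38),
        (1340.0, 10.0, 0.30),
        (1450.0, 10.0, 0.55),
        (1655.0, 12.0, 0.78),
    ],
    "fibrosis": [
        (860.0, 9.0, 0.62),
        (938.0, 9.0, 0.60),
        (1004.0, 5.0, 0.40),
        (1245.0, 11.0, 0.42),
        (1270.0, 10.0, 0.36),
        (1450.0, 10.0, 0.52),
        (1655.0, 12.0, 0.70),
    ],
}

#: Default photon-count scale: band of relative amplitude 1 peaks at this
#: many counts (3.5 s acquisition at 785 nm, order-of-magnitude realistic).
RAMAN_COUNT_SCALE = 1000.0

#: Default white-noise standard deviation, counts.
RAMAN_NOISE_SD = 8.0

#: Default probability that a spectrum contains one cosmic-ray spike.
COSMIC_RAY_RATE = 0.1
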