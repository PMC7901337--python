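"""Seeded synthetic-specimen generator.

Everything downstream of the instrument — the ratiometric screening, the
sampling planner, the spectral processing chain and the classifier — is
exercised on specimens produced here: labelled tissue mosaics
(adipose / stroma / tumour / fibrosis on a background), the two
band-pass-filtered wide-field autofluorescence images a TIR waveguide
imager would record, and per-point fingerprint Raman spectra.  All
randomness flows from explicit integer seeds, so any rendered specimen is
bit-reproducible.

The generator deliberately models only what the analysis relies on:
per-class emission mixtures and Raman band models (see
:mod:`aframan.profiles`), channel-common multiplicative blood/contact
variation (which the ratiometric step is designed to cancel), Gaussian
detector noise, a smooth fluorescence baseline and rare cosmic-ray
spikes.  It does not simulate optics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
from scipy.ndimage import gaussian_filter, label as cc_label
from scipy.special import ndtr

from . import profiles
from .ramanproc import RamanSpectrum


class Tissue(IntEnum):
    """Tissue-class codes used in label grids."""

    BACKGROUND = 0
    ADIPOSE = 1
    STROMA = 2
    TUMOUR = 3
    FIBROSIS = 4


#: Classes that carry spectral models (everything but background).
SPECIMEN_CLASSES = ("adipose", "stroma", "tumour", "fibrosis")


def _class_name(code: int) -> str:
    return Tissue(code).name.lower()


# ---------------------------------------------------------------------------
# region primitives


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle, inclusive pixel bounds."""

    tissue: Tissue
    row0: int
    col0: int
    row1: int
    col1: int
    name: str = "rect"


@dataclass(frozen=True)
class Disc:
    """Disc defined on pixel centers: (r-row)^2 + (c-col)^2 <= radius^2."""

    tissue: Tissue
    row: float
    col: float
    radius: float
    name: str = "disc"


@dataclass(frozen=True)
class Annulus:
    """Annular ring on pixel centers, r_in < distance <= r_out."""

    tissue: Tissue
    row: float
    col: float
    r_in: float
    r_out: float
    name: str = "annulus"


Region = Rect | Disc | Annulus


def _rasterise(region: Region, shape: tuple[int, int]) -> np.ndarray:
    rows, cols = np.indices(shape)
    if isinstance(region, Rect):
        return (
            (rows >= region.row0)
            & (rows <= region.row1)
            & (cols >= region.col0)
            & (cols <= region.col1)
        )
    d2 = (rows - region.row) ** 2 + (cols - region.col) ** 2
    if isinstance(region, Disc):
        return d2 <= region.radius**2
    return (d2 > region.r_in**2) & (d2 <= region.r_out**2)


# ---------------------------------------------------------------------------
# tissue map


@dataclass(frozen=True)
class TissueMap:
    """Ground-truth labelled mosaic of a (virtual) specimen surface.

    ``labels`` holds one :class:`Tissue` code per pixel; background is
    exactly the complement of the specimen.  ``pixel_size_um`` is the
    physical pixel pitch (default 50 um, matching typical Raman sampling
    step sizes on this kind of instrument).
    """

    labels: np.ndarray
    pixel_size_um: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValueError("labels must be a 2-D grid")
        object.__setattr__(self, "labels", lab.astype(np.uint8))

    @property
    def specimen_mask(self) -> np.ndarray:
        return self.labels != Tissue.BACKGROUND

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def class_fractions(self) -> dict[str, float]:
        n = max(int(self.specimen_mask.sum()), 1)
        return {
            name: float((self.labels == code).sum()) / n
            for code, name in ((t.value, t.name.lower()) for t in Tissue)
            if code != Tissue.BACKGROUND
        }


def make_tissue_map(
    shape: tuple[int, int],
    region_spec: list[Region],
    seed: int = 0,
    pixel_size_um: float = 50.0,
) -> TissueMap:
    """Paint labelled geometric primitives onto a background grid.

    Primitives are painted in list order (later ones overwrite earlier
    ones).  Painting a background primitive over previously painted tumour
    is rejected: it would silently carve tumour out of the specimen.
    """
    if len(shape) != 2 or shape[0] <= 0 or shape[1] <= 0:
        raise ValueError("shape must be two positive integers")
    labels = np.zeros(shape, dtype=np.uint8)
    for region in region_spec:
        m = _rasterise(region, shape)
        if not m.any():
            raise ValueError(f"region {region.name!r} lies outside the {shape} grid")
        if region.tissue == Tissue.BACKGROUND and np.any(
            (labels == Tissue.TUMOUR) & m
        ):
            prior = [
                r.name
                for r in region_spec
                if r.tissue == Tissue.TUMOUR and np.any(_rasterise(r, shape) & m)
            ]
            raise ValueError(
                f"background region {region.name!r} overlaps tumour region(s) {prior}"
            )
        labels[m] = region.tissue
    tmap = TissueMap(labels=labels, pixel_size_um=pixel_size_um, seed=seed)
    # tumour components must sit fully inside the specimen (they do by
    # construction since tumour is itself a specimen label; assert anyway)
    comp, _ = cc_label(tmap.labels == Tissue.TUMOUR)
    assert np.all(tmap.specimen_mask[comp > 0])
    return tmap


def demo_tissue_map(
    shape: tuple[int, int] = (200, 200),
    tumour_radius_px: float = 35.0,
    stroma_halo_px: float = 18.0,
    seed: int = 0,
    pixel_size_um: float = 50.0,
    fibrosis: bool = False,
) -> TissueMap:
    """A realistic demo mosaic: adipose specimen with a stroma-haloed tumour.

    Mirrors the common presentation of an excision surface — a large
    adipose field with a central tumour surrounded by reactive stroma; a
    1-pixel background frame keeps the specimen edge inside the image.
    """
    r0, c0 = shape[0] / 2, shape[1] / 2
    regions: list[Region] = [
        Rect(Tissue.ADIPOSE, 1, 1, shape[0] - 2, shape[1] - 2, name="specimen"),
        Annulus(
            Tissue.FIBROSIS if fibrosis else Tissue.STROMA,
            r0,
            c0,
            tumour_radius_px,
            tumour_radius_px + stroma_halo_px,
            name="halo",
        ),
        Disc(Tissue.TUMOUR, r0, c0, tumour_radius_px, name="tumour"),
    ]
    return make_tissue_map(shape, regions, seed=seed, pixel_size_um=pixel_size_um)


# ---------------------------------------------------------------------------
# emission profiles and AF rendering


@dataclass(frozen=True)
class EmissionProfile:
    """A tissue-class emission spectrum as a sum of Gaussian components."""

    tissue: str
    components: tuple[tuple[float, float, float], ...]
    wavelength_nm: np.ndarray
    intensity: np.ndarray

    def band_integral(self, lo_nm: float, hi_nm: float) -> float:
        """Exact integral of the component mixture over a passband.

        Uses the Gaussian closed form (erf) rather than quadrature on the
        sampled grid, so rendered intensities are grid-independent.
        """
        m = (self.wavelength_nm >= lo_nm) & (self.wavelength_nm <= hi_nm)
        if not m.any():
            raise ValueError(
                f"passband {lo_nm}-{hi_nm} nm does not overlap the emission grid"
            )
        total = 0.0
        for center, sigma, amp in self.components:
            total += (
                amp
                * sigma
                * np.sqrt(2 * np.pi)
                * (ndtr((hi_nm - center) / sigma) - ndtr((lo_nm - center) / sigma))
            )
        return float(total)


def emission_profile(
    tissue_class: str | Tissue, wavelength_nm: np.ndarray | None = None
) -> EmissionProfile:
    """Calibrated 365 nm-excited emission profile for one tissue class."""
    name = (
        _class_name(tissue_class)
        if isinstance(tissue_class, (int, Tissue))
        else str(tissue_class).lower()
    )
    if name not in profiles.EMISSION_COMPONENTS:
        raise ValueError(
            f"unknown tissue class {tissue_class!r}; expected one of {SPECIMEN_CLASSES}"
        )
    grid = profiles.WAVELENGTH_GRID_NM if wavelength_nm is None else np.asarray(wavelength_nm, float)
    comps = tuple(profiles.EMISSION_COMPONENTS[name])
    y = np.zeros_like(grid)
    for center, sigma, amp in comps:
        y += amp * np.exp(-0.5 * ((grid - center) / sigma) ** 2)
    return EmissionProfile(
        tissue=name, components=comps, wavelength_nm=grid, intensity=y
    )


@dataclass(frozen=True)
class AFImagePair:
    """Co-registered Filter 1 / Filter 2 wide-field AF intensity rasters."""

    filter1: np.ndarray
    filter2: np.ndarray
    filter1_band_nm: tuple[float, float]
    filter2_band_nm: tuple[float, float]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.filter1.shape != self.filter2.shape:
            raise ValueError("channels must be co-registered (same shape)")


#: Detection passbands of the two emission filters, nm.
FILTER1_NM = (442.0, 488.0)
FILTER2_NM = (480.0, 562.0)


def class_band_ratios(
    filter1_nm: tuple[float, float] = FILTER1_NM,
    filter2_nm: tuple[float, float] = FILTER2_NM,
) -> dict[str, float]:
    """Noiseless Filter1/Filter2 band-integral ratio per tissue class."""
    out = {}
    for name in SPECIMEN_CLASSES:
        p = emission_profile(name)
        out[name] = p.band_integral(*filter1_nm) / p.band_integral(*filter2_nm)
    return out


def smooth_random_field(
    shape: tuple[int, int],
    rng: np.random.Generator,
    lo: float,
    hi: float,
    correlation_px: float = 25.0,
) -> np.ndarray:
    """Spatially correlated random field rescaled to [lo, hi]."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=correlation_px)
    f = f - f.min()
    peak = f.max()
    if peak > 0:
        f = f / peak
    return lo + (hi - lo) * f


def render_af_pair(
    tmap: TissueMap,
    filter1_nm: tuple[float, float] = FILTER1_NM,
    filter2_nm: tuple[float, float] = FILTER2_NM,
    noise_sd: float = 0.02,
    blood_field: np.ndarray | None = None,
    contact_field: np.ndarray | None = None,
    seed: int = 0,
    peak_counts: float = 25000.0,
) -> AFImagePair:
    """Render the two filtered AF images of a tissue map.

    Per pixel, each channel integrates the class emission profile over its
    passband, multiplied by the (channel-common) contact-quality gain and
    blood transmission fields, plus Gaussian noise of standard deviation
    ``noise_sd`` times the brightest noiseless intensity; negative counts
    are clipped to zero.  Background pixels are dark.
    """
    grid = profiles.WAVELENGTH_GRID_NM
    for lo, hi in (filter1_nm, filter2_nm):
        if hi <= grid[0] or lo >= grid[-1]:
            raise ValueError(f"passband {lo}-{hi} nm outside the emission grid")
    integ = {
        name: (
            emission_profile(name).band_integral(*filter1_nm),
            emission_profile(name).band_integral(*filter2_nm),
        )
        for name in SPECIMEN_CLASSES
    }
    gain = peak_counts / max(v for pair in integ.values() for v in pair)
    ch1 = np.zeros(tmap.shape, dtype=float)
    ch2 = np.zeros(tmap.shape, dtype=float)
    for name, (i1, i2) in integ.items():
        m = tmap.labels == Tissue[name.upper()]
        ch1[m] = i1 * gain
        ch2[m] = i2 * gain
    for fld in (blood_field, contact_field):
        if fld is not None:
            if fld.shape != tmap.shape:
                raise ValueError("field shape must match the tissue map")
            ch1 = ch1 * fld
            ch2 = ch2 * fld
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        scale = noise_sd * max(ch1.max(), ch2.max())
        ch1 = ch1 + rng.normal(0.0, scale, tmap.shape)
        ch2 = ch2 + rng.normal(0.0, scale, tmap.shape)
    ch1 = np.clip(ch1, 0.0, None)
    ch2 = np.clip(ch2, 0.0, None)
    return AFImagePair(
        filter1=ch1,
        filter2=ch2,
        filter1_band_nm=filter1_nm,
        filter2_band_nm=filter2_nm,
        meta={"seed": seed, "noise_sd": noise_sd, "pixel_size_um": tmap.pixel_size_um},
    )


# ---------------------------------------------------------------------------
# Raman rendering


@dataclass(frozen=True)
class RamanBandModel:
    """Per-class generative Raman model: bands + baseline + noise + spikes."""

    tissue: str
    bands: tuple[tuple[float, float, float], ...]
    count_scale: float = profiles.RAMAN_COUNT_SCALE
    baseline_fraction: float = 0.3
    noise_sd: float = profiles.RAMAN_NOISE_SD
    cosmic_ray_rate: float = profiles.COSMIC_RAY_RATE

    def __post_init__(self) -> None:
        for c, w, a in self.bands:
            if not 600 <= c <= 1800:
                raise ValueError(f"band center {c} outside 600-1800 cm^-1")
            if a <= 0 or w <= 0:
                raise ValueError("band widths and amplitudes must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def default_band_models(
    noise_sd: float = profiles.RAMAN_NOISE_SD,
    cosmic_ray_rate: float = profiles.COSMIC_RAY_RATE,
    baseline_fraction: float = 0.3,
) -> dict[str, RamanBandModel]:
    """The calibrated per-class band models from the versioned table."""
    return {
        name: RamanBandModel(
            tissue=name,
            bands=tuple(profiles.RAMAN_BANDS[name]),
            noise_sd=noise_sd,
            cosmic_ray_rate=cosmic_ray_rate,
            baseline_fraction=baseline_fraction,
        )
        for name in SPECIMEN_CLASSES
    }


def band_sum(
    model: RamanBandModel, wavenumber: np.ndarray | None = None
) -> np.ndarray:
    """Pure (noiseless, baseline-free) band-sum spectrum of a model."""
    wn = profiles.RAMAN_GRID_CM1 if wavenumber is None else np.asarray(wavenumber, float)
    y = np.zeros_like(wn)
    for center, sigma, amp in model.bands:
        y += amp * np.exp(-0.5 * ((wn - center) / sigma) ** 2)
    return y * model.count_scale


def render_raman(
    point: tuple[int, int],
    tmap: TissueMap,
    model_set: dict[str, RamanBandModel] | None = None,
    seed: int = 0,
    acquisition_s: float = 3.5,
    wavenumber: np.ndarray | None = None,
) -> RamanSpectrum:
    """Render the Raman spectrum acquired at one specimen point.

    The spectrum is the class band sum plus a smooth random cubic
    baseline (bounded by ``baseline_fraction`` of the tallest band), white
    Gaussian noise, and — with probability ``cosmic_ray_rate`` — a single
    1-3 channel cosmic-ray spike at least 10x the tallest band.  The
    ground-truth class is attached as metadata.
    """
    r, c = int(point[0]), int(point[1])
    if not (0 <= r < tmap.shape[0] and 0 <= c < tmap.shape[1]) or not tmap.specimen_mask[r, c]:
        raise ValueError(f"point {point} is outside the specimen")
    models = default_band_models() if model_set is None else model_set
    cls = _class_name(tmap.labels[r, c])
    model = models[cls]
    wn = profiles.RAMAN_GRID_CM1 if wavenumber is None else np.asarray(wavenumber, float)
    rng = np.random.default_rng(seed)
    y = band_sum(model, wn)
    peak = float(max(a for _, _, a in model.bands)) * model.count_scale

    if model.baseline_fraction > 0:
        x = np.linspace(-1.0, 1.0, wn.size)
        coeffs = rng.uniform(-1.0, 1.0, size=4)
        base = np.polynomial.polynomial.polyval(x, coeffs)
        base = base - base.min()
        top = base.max()
        if top > 0:
            amp = model.baseline_fraction * peak * rng.uniform(0.5, 1.0)
            base = base / top * amp
        y = y + base
    if model.noise_sd > 0:
        y = y + rng.normal(0.0, model.noise_sd, wn.size)
    cosmic = False
    if rng.uniform() < model.cosmic_ray_rate:
        cosmic = True
        width = int(rng.integers(1, 4))
        start = int(rng.integers(3, wn.size - width - 3))
        y[start : start + width] += peak * rng.uniform(10.0, 20.0)
    return RamanSpectrum(
        wavenumber=wn,
        counts=y,
        meta={
            "point": (r, c),
            "true_class": cls,
            "seed": seed,
            "acquisition_s": acquisition_s,
            "cosmic_ray_injected": cosmic,
        },
    )


# ---------------------------------------------------------------------------
# synthetic instrument imperfections (what the processing chain corrects)


@dataclass(frozen=True)
class InstrumentModel:
    """Mild spectrograph imperfections applied to 'as-acquired' spectra.

    ``response_curvature`` bends the relative intensity response (1 at the
    band center, reduced towards the edges); ``axis_offset_cm1`` and
    ``axis_stretch`` mis-set the nominal shift axis the way a drifting
    spectrograph would.
    """

    response_curvature: float = 0.3
    axis_offset_cm1: float = 2.0
    axis_stretch: float = 1.0

    def response(self, wavenumber: np.ndarray) -> np.ndarray:
        x = (wavenumber - 1200.0) / 600.0
        return 1.0 - self.response_curvature * x**2

    def true_shift(self, nominal: np.ndarray) -> np.ndarray:
        return self.axis_stretch * np.asarray(nominal, float) + self.axis_offset_cm1

    def distort(self, s: RamanSpectrum) -> RamanSpectrum:
        """True spectrum -> what the instrument reports on its nominal axis.

        The reported channel labelled ``v`` actually observed the true
        shift ``stretch * v + offset``, with the bent intensity response
        applied; wavenumber calibration must invert exactly this map.
        """
        counts = s.counts * self.response(s.wavenumber)
        reported = np.interp(self.true_shift(s.wavenumber), s.wavenumber, counts)
        return s.evolve(counts=reported, step="instrument_distortion")
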