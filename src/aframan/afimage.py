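"""Ratiometric TIR-AF image construction and adipose screening.

The two filtered autofluorescence images are masked to the specimen,
divided channel-wise (Filter 1 / Filter 2), and the resulting ratio image
is partitioned by multi-level thresholding.  On 365 nm-excited breast
tissue the adipose ratio falls in 0.2-0.8 while stroma and tumour fall in
0.8-2, so a single threshold at 0.8 screens adipose out of the Raman
sampling; specimens with extended fibrosis use a retained band of 1-2
instead.  Because the quotient cancels channel-common factors (blood
absorption, contact quality, illumination), the screening is insensitive
to them by construction.

Interval convention: all ratio bands are half-open ``[lo, hi)``.  A pixel
at exactly the 0.8 threshold is therefore *retained* for Raman sampling —
over-retention is the safe direction, since retained adipose merely costs
measurement time while screened-out tumour would be missed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
from scipy.ndimage import median_filter
from skimage.filters import threshold_otsu

from .phantom import AFImagePair


class ScreenLabel(IntEnum):
    """Per-pixel screening outcome."""

    UNMASKED = 0
    ADIPOSE = 1
    RETAINED = 2
    OUT_OF_RANGE = 3


@dataclass(frozen=True)
class FilterBand:
    """An emission filter passband in nm."""

    lo: float
    hi: float
    name: str = ""

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError("passband requires lo < hi")


@dataclass(frozen=True)
class ThresholdBands:
    """Ratio intervals used for screening, half-open ``[lo, hi)``.

    With ``fibrosis_mode`` off the adipose and retained bands share the
    0.8 edge (0.2-0.8 and 0.8-2); with it on, the retained band narrows to
    1-2 and the 0.8-1 gap (fibrosis-like ratios) is excluded.
    """

    adipose: tuple[float, float] = (0.2, 0.8)
    retained: tuple[float, float] = (0.8, 2.0)
    fibrosis_mode: bool = False

    def __post_init__(self) -> None:
        if self.fibrosis_mode and self.retained == (0.8, 2.0):
            object.__setattr__(self, "retained", (1.0, 2.0))
        if not self.fibrosis_mode and self.adipose[1] != self.retained[0]:
            raise ValueError("adipose.hi must equal retained.lo unless fibrosis_mode")
        if self.adipose[0] >= self.adipose[1] or self.retained[0] >= self.retained[1]:
            raise ValueError("band intervals must be non-empty")


@dataclass(frozen=True)
class RatiometricImage:
    """Masked per-pixel Filter1/Filter2 quotient.

    ``ratio`` is NaN outside the mask; ``provenance`` records where the
    channels came from and how many pixels were dropped for a dark
    denominator.
    """

    ratio: np.ndarray
    mask: np.ndarray
    mask_threshold: float
    provenance: dict = field(default_factory=dict)

    def masked_values(self) -> np.ndarray:
        return self.ratio[self.mask]


def suggest_mask_threshold(channel: np.ndarray) -> float:
    """Otsu's threshold on the masking channel, offered as a starting point.

    The operator's manually chosen value always wins; this is a suggestion
    for where to start.  Note Otsu optimises between-class contrast and can
    split bright from dim *tissue* rather than tissue from background when
    the background area is small — use :func:`auto_mask_threshold` for
    unattended runs.
    """
    return float(threshold_otsu(np.asarray(channel, float)))


def auto_mask_threshold(channel: np.ndarray, fraction: float = 0.15) -> float:
    """Unattended background threshold: a fraction of the bright reference.

    On a dark-field (evanescent-excitation) image, pixels without tissue
    contact sit near zero while every tissue class is a sizeable fraction
    of the brightest signal, so a fixed fraction of the 99.9th-percentile
    intensity separates background from specimen robustly regardless of
    tissue composition.
    """
    return float(fraction * np.percentile(np.asarray(channel, float), 99.9))


def mask_background(channel: np.ndarray, threshold: float) -> np.ndarray:
    """Specimen mask: pixels at or above the intensity threshold.

    Monotone in the threshold (raising it never adds pixels).  An empty
    result warns rather than raising: the operator simply set the
    threshold above the image maximum.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    channel = np.asarray(channel, float)
    mask = channel >= threshold
    if not mask.any():
        warnings.warn(
            f"mask threshold {threshold} exceeds the image maximum "
            f"({channel.max():.1f}); mask is empty",
            RuntimeWarning,
        )
    return mask


def ratiometric(
    pair: AFImagePair,
    mask: np.ndarray,
    epsilon: float = 1.0,
) -> RatiometricImage:
    """Divide Filter 1 by Filter 2 over the mask.

    Pixels whose Filter 2 intensity is at or below ``epsilon`` counts are
    removed from the mask (division would be meaningless) and counted in
    provenance.
    """
    if pair.filter1.shape != mask.shape:
        raise ValueError("mask shape must match the image pair")
    denom_ok = pair.filter2 > epsilon
    effective = mask & denom_ok
    dropped = int(mask.sum() - effective.sum())
    ratio = np.full(pair.filter1.shape, np.nan)
    ratio[effective] = pair.filter1[effective] / pair.filter2[effective]
    return RatiometricImage(
        ratio=ratio,
        mask=effective,
        mask_threshold=float(epsilon),
        provenance={
            "filter1_band_nm": pair.filter1_band_nm,
            "filter2_band_nm": pair.filter2_band_nm,
            "epsilon_counts": float(epsilon),
            "n_low_denominator": dropped,
        },
    )


def screen_adipose(
    rimg: RatiometricImage,
    bands: ThresholdBands | None = None,
    median_filter_3x3: bool = False,
) -> np.ndarray:
    """Label each masked pixel adipose / retained / out-of-range.

    The three labels partition the mask exactly: every masked pixel gets
    one label, and unmasked pixels stay ``UNMASKED``.  Pixels with ratio
    at or above the retained upper edge (2 by default) are out of range
    and excluded from Raman sampling, as are sub-adipose ratios.
    """
    bands = bands or ThresholdBands()
    ratio = rimg.ratio
    if median_filter_3x3:
        filled = np.where(rimg.mask, ratio, 0.0)
        ratio = np.where(rimg.mask, median_filter(filled, size=3), np.nan)
    labels = np.full(ratio.shape, ScreenLabel.UNMASKED, dtype=np.uint8)
    m = rimg.mask
    labels[m] = ScreenLabel.OUT_OF_RANGE
    adip = m & (ratio >= bands.adipose[0]) & (ratio < bands.adipose[1])
    ret = m & (ratio >= bands.retained[0]) & (ratio < bands.retained[1])
    labels[adip] = ScreenLabel.ADIPOSE
    labels[ret] = ScreenLabel.RETAINED
    return labels


def multilevel_threshold_report(
    rimg: RatiometricImage, band_edges: list[float]
) -> dict:
    """Partition the masked ratio image into intervals between the edges.

    Returns one binary image per half-open interval ``[e_i, e_{i+1})``
    plus below/above-range masks; the reported area fractions (over the
    mask) sum to one.
    """
    edges = np.asarray(band_edges, float)
    if edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("band edges must be at least two strictly increasing values")
    m = rimg.mask
    n_mask = int(m.sum())
    intervals = [(float(lo), float(hi)) for lo, hi in zip(edges[:-1], edges[1:])]
    images = [
        m & (rimg.ratio >= lo) & (rimg.ratio < hi) for lo, hi in intervals
    ]
    below = m & (rimg.ratio < edges[0])
    above = m & (rimg.ratio >= edges[-1])
    denom = max(n_mask, 1)
    fractions = [float(img.sum()) / denom for img in images]
    return {
        "intervals": intervals,
        "images": images,
        "area_fractions": fractions,
        "below_fraction": float(below.sum()) / denom,
        "above_fraction": float(above.sum()) / denom,
        "n_masked_px": n_mask,
    }
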