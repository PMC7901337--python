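"""File interchange: TIFF/PNG rasters, CSV spectra and run manifests."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .phantom import Tissue
from .ramanproc import RamanSpectrum

LABEL_LEGEND = {int(t.value): t.name.lower() for t in Tissue}


def write_af_channel(path: Path, channel: np.ndarray) -> None:
    """Write one AF channel as 16-bit grayscale TIFF (counts clipped to range)."""
    data = np.clip(np.asarray(channel), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data)


def read_af_channel(path: Path) -> np.ndarray:
    return tifffile.imread(path).astype(float)


def write_ratio_image(path: Path, ratio: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(ratio, dtype=np.float32))


def read_ratio_image(path: Path) -> np.ndarray:
    return tifffile.imread(path).astype(float)


def write_label_png(path: Path, labels: np.ndarray, legend_path: Path | None = None) -> None:
    """8-bit indexed label raster plus a JSON legend mapping codes to names."""
    iio.imwrite(path, np.asarray(labels, dtype=np.uint8))
    if legend_path is not None:
        legend_path.write_text(json.dumps(LABEL_LEGEND, indent=2, sort_keys=True) + "\n")


def read_label_png(path: Path) -> np.ndarray:
    arr = iio.imread(path)
    if arr.ndim == 3:  # grayscale PNG readers may expand channels
        arr = arr[..., 0]
    return arr.astype(np.uint8)


def write_spectrum_csv(path: Path, s: RamanSpectrum) -> None:
    pd.DataFrame({"wavenumber_cm-1": s.wavenumber, "counts": s.counts}).to_csv(
        path, index=False
    )


def read_spectrum_csv(path: Path, meta: dict | None = None) -> RamanSpectrum:
    df = pd.read_csv(path)
    return RamanSpectrum(
        wavenumber=df["wavenumber_cm-1"].to_numpy(),
        counts=df["counts"].to_numpy(),
        meta=meta or {},
    )


def sha256_of(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(path: Path, entries: dict) -> None:
    path.write_text(json.dumps(entries, indent=2, sort_keys=True) + "\n")
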