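"""File I/O: 8-bit channel TIFFs, 16-bit label masks, decay CSVs, renders."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .cells import SegmentationLabels
from .flim import DecayHistogram
from .polarization import PolarizedImagePair


def write_channel(path, image: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(image, dtype=np.uint8))


def read_channel(path) -> np.ndarray:
    img = tifffile.imread(str(path))
    if img.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel 2-D image")
    return img


def write_labels(path, labels: np.ndarray) -> None:
    arr = np.asarray(labels)
    if arr.min() < 0 or arr.max() > np.iinfo(np.uint16).max:
        raise ValueError("label IDs out of uint16 range")
    tifffile.imwrite(str(path), arr.astype(np.uint16))


def read_labels(path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(np.int32)


def read_pair(co_path, cross_path) -> PolarizedImagePair:
    return PolarizedImagePair(co=read_channel(co_path), cross=read_channel(cross_path))


def read_segmentation(cell_path, nucleus_path) -> SegmentationLabels:
    return SegmentationLabels(cell_labels=read_labels(cell_path),
                              nucleus_labels=read_labels(nucleus_path))


def write_float_map(path, values: np.ndarray) -> None:
    """Fpol / lifetime maps as 32-bit float TIFF (NaN outside validity)."""
    tifffile.imwrite(str(path), np.asarray(values, dtype=np.float32))


def write_render(path, rgb: np.ndarray) -> None:
    iio.imwrite(str(path), np.asarray(rgb, dtype=np.uint8))


def write_decay(path, hist: DecayHistogram) -> None:
    """Decay CSV with columns bin_start_ns, counts, irf."""
    n = hist.n_bins
    df = pd.DataFrame({
        "bin_start_ns": hist.t0_ns + np.arange(n) * hist.bin_width_ns,
        "counts": hist.counts,
        "irf": hist.irf if hist.irf is not None else np.full(n, np.nan),
    })
    df.to_csv(Path(path), index=False)


def read_decay(path) -> DecayHistogram:
    df = pd.read_csv(Path(path))
    starts = df["bin_start_ns"].to_numpy(dtype=float)
    if len(starts) < 2:
        raise ValueError(f"{path}: decay needs at least 2 bins")
    dt = float(np.median(np.diff(starts)))
    irf = df["irf"].to_numpy(dtype=float) if "irf" in df else None
    if irf is not None and np.isnan(irf).all():
        irf = None
    return DecayHistogram(
        counts=df["counts"].to_numpy(dtype=np.int64),
        bin_width_ns=dt, t0_ns=float(starts[0]), irf=irf,
    )
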