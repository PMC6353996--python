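"""Per-cell co-localization of the dye channel with organelle trackers.

Co-localization is quantified with the sample Pearson correlation of paired
pixel intensities inside each cell's ROI (whole-cell mask intersected with
any validity mask).  Only Pearson's R is reported; Manders/Costes statistics
are out of scope.  An optional Otsu sub-ROI mode restricts the ROI to the
bright organelle-channel pixels for sensitivity analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .cells import DEFAULT_MIN_PIXELS, SegmentationLabels, _border_ids

logger = logging.getLogger(__name__)

__all__ = ["ColocRecord", "pearson_r", "coloc_table"]


@dataclass(frozen=True)
class ColocRecord:
    cell_id: int
    organelle: str
    pearson_r: float
    n_pixels: int


def pearson_r(
    channel_a: np.ndarray,
    channel_b: np.ndarray,
    roi: np.ndarray,
    min_pixels: int = DEFAULT_MIN_PIXELS,
) -> float:
    """Sample Pearson correlation of two channels over an ROI.

    Raises on an empty/too-small ROI or on a constant channel (correlation
    undefined — never silently 0).
    """
    if channel_a.shape != channel_b.shape or channel_a.shape != roi.shape:
        raise ValueError("channels and ROI must share a shape")
    a = channel_a[roi].astype(float)
    b = channel_b[roi].astype(float)
    if a.size < min_pixels:
        raise ValueError(f"ROI has {a.size} pixels < min_pixels={min_pixels}")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant channel within ROI: correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])


def coloc_table(
    channels: Mapping[str, np.ndarray],
    labels: SegmentationLabels,
    organelle_channel_map: Mapping[str, str],
    mb_channel: str = "mb",
    valid_mask: np.ndarray | None = None,
    min_pixels: int = DEFAULT_MIN_PIXELS,
    exclude_border: bool = True,
) -> pd.DataFrame:
    """One Pearson-R record per (cell, organelle).

    ``organelle_channel_map`` maps organelle names (e.g. ``mitochondria``)
    to channel names in ``channels``; ``mb_channel`` names the dye channel.
    The ROI is each cell's whole mask, optionally intersected with
    ``valid_mask``.  Cells whose ROI is too small or degenerate (constant
    channel) are skipped with a log message.
    """
    if mb_channel not in channels:
        raise KeyError(f"dye channel {mb_channel!r} missing from stack")
    for org, ch in organelle_channel_map.items():
        if ch not in channels:
            raise KeyError(f"channel {ch!r} for organelle {org!r} missing from stack")
    mb = channels[mb_channel]
    skip = _border_ids(labels.cell_labels) if exclude_border else set()
    rows: list[ColocRecord] = []
    for cid in labels.cell_ids:
        cid = int(cid)
        if cid in skip:
            continue
        roi = labels.cell_labels == cid
        if valid_mask is not None:
            roi &= valid_mask
        for organelle, ch in organelle_channel_map.items():
            try:
                r = pearson_r(mb, channels[ch], roi, min_pixels=min_pixels)
            except ValueError as exc:
                logger.info("cell %d / %s skipped: %s", cid, organelle, exc)
                continue
            rows.append(ColocRecord(cid, organelle, r, int(roi.sum())))
    return pd.DataFrame(
        [r.__dict__ for r in rows],
        columns=["cell_id", "organelle", "pearson_r", "n_pixels"],
    )


def organelle_subroi(organelle_channel: np.ndarray, roi: np.ndarray) -> np.ndarray:
    """Optional Otsu sub-ROI: bright organelle pixels within the cell ROI."""
    from skimage.filters import threshold_otsu

    vals = organelle_channel[roi]
    if vals.size == 0 or np.ptp(vals) == 0:
        return roi.copy()
    thr = threshold_otsu(vals.astype(float))
    return roi & (organelle_channel > thr)
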