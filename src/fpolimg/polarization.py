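"""Pixel-wise fluorescence polarization (Fpol) with G-factor correction.

The central quantity is the fluorescence polarization of a pixel (or of a
mean intensity pair)::

    Fpol = (I_co - G * I_cross) / (I_co + G * I_cross)

where ``I_co`` and ``I_cross`` are the co- and cross-polarized emission
intensities recorded by two detectors behind a polarizing beam splitter, and
``G`` is the instrument G-factor correcting for the unequal sensitivity of
the two detection channels.  ``G`` is estimated from a reference sample with
known (zero) polarization: a freely rotating dye in a non-viscous solvent
fully depolarizes, so ``G = mean(I_co) / mean(I_cross)`` over that reference.

Images are 8-bit; pixels are thresholded (inclusive low/high bounds, jointly
in both channels) to drop background and saturated pixels before any Fpol
statistic is formed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Union

import numpy as np
from matplotlib.colors import LinearSegmentedColormap

logger = logging.getLogger(__name__)

__all__ = [
    "PolarizedImagePair",
    "GFactor",
    "ThresholdRule",
    "FpolMap",
    "compute_fpol",
    "apply_threshold",
    "fpol_map",
    "render_fpol",
    "calibrate_g",
    "fpol_lut",
]

#: default display range of pseudo-colored Fpol images
FPOL_RENDER_RANGE = (0.0, 0.34)


@dataclass(frozen=True)
class GFactor:
    """Instrument G-factor (unitless, > 0)."""

    value: float
    source: str = "configured"  # "configured" | "calibrated"

    def __post_init__(self) -> None:
        if not np.isfinite(self.value) or self.value <= 0:
            raise ValueError(f"G-factor must be finite and > 0, got {self.value}")


@dataclass(frozen=True)
class ThresholdRule:
    """Inclusive 8-bit intensity bounds; pixels outside are invalid."""

    low: int = 2
    high: int = 254

    def __post_init__(self) -> None:
        if not (0 <= self.low <= self.high <= 255):
            raise ValueError(f"require 0 <= low <= high <= 255, got {self}")


@dataclass
class PolarizedImagePair:
    """Registered co-/cross-polarized 8-bit image pair."""

    co: np.ndarray
    cross: np.ndarray
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        self.co = np.asarray(self.co)
        self.cross = np.asarray(self.cross)
        if self.co.shape != self.cross.shape:
            raise ValueError(
                f"channel shapes differ: co {self.co.shape} vs cross {self.cross.shape}"
            )
        for name, arr in (("co", self.co), ("cross", self.cross)):
            if arr.min() < 0 or arr.max() > 255:
                raise ValueError(f"{name} channel outside 8-bit range [0, 255]")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.co.shape


@dataclass
class FpolMap:
    """Pixel-wise Fpol plus the emission/difference intermediates.

    ``fpol`` is NaN outside ``valid_mask``.  ``emission`` is
    ``I_co + G * I_cross`` and ``difference`` is ``I_co - G * I_cross``;
    both are kept in floating point (no 8-bit re-rounding).
    """

    fpol: np.ndarray
    valid_mask: np.ndarray
    emission: np.ndarray
    difference: np.ndarray
    g: GFactor = field(default_factory=lambda: GFactor(1.0))


GLike = Union[GFactor, float]


def _g_value(g: GLike) -> float:
    if isinstance(g, GFactor):
        return g.value
    g = float(g)
    if not np.isfinite(g) or g <= 0:
        raise ValueError(f"G-factor must be finite and > 0, got {g}")
    return g


def compute_fpol(i_co, i_cross, g: GLike):
    """Fpol of an intensity pair: ``(I_co - G I_cross) / (I_co + G I_cross)``.

    Accepts scalars or arrays.  Raises if any denominator is zero (an
    undefined Fpol is never silently reported as 0).
    """
    gval = _g_value(g)
    i_co = np.asarray(i_co, dtype=float)
    i_cross = np.asarray(i_cross, dtype=float)
    if np.any(i_co < 0) or np.any(i_cross < 0):
        raise ValueError("intensities must be nonnegative")
    denom = i_co + gval * i_cross
    if np.any(denom == 0):
        raise ZeroDivisionError("Fpol undefined where I_co + G*I_cross == 0")
    out = (i_co - gval * i_cross) / denom
    return out if out.ndim else float(out)


def apply_threshold(pair: PolarizedImagePair, rule: ThresholdRule = ThresholdRule()) -> np.ndarray:
    """Joint validity mask: pixel valid iff within [low, high] in BOTH channels."""
    mask = (
        (pair.co >= rule.low)
        & (pair.co <= rule.high)
        & (pair.cross >= rule.low)
        & (pair.cross <= rule.high)
    )
    if not mask.any():
        logger.warning("threshold %s leaves no valid pixels", rule)
    return mask


def fpol_map(
    pair: PolarizedImagePair,
    g: GLike,
    rule: ThresholdRule = ThresholdRule(),
) -> FpolMap:
    """Pixel-by-pixel Fpol map over pixels passing the threshold rule."""
    gval = _g_value(g)
    valid = apply_threshold(pair, rule)
    co = pair.co.astype(float)
    cross = pair.cross.astype(float)
    emission = co + gval * cross
    difference = co - gval * cross
    fpol = np.full(pair.shape, np.nan)
    np.divide(difference, emission, out=fpol, where=valid & (emission > 0))
    fpol[~valid] = np.nan
    return FpolMap(fpol=fpol, valid_mask=valid, emission=emission,
                   difference=difference, g=GFactor(gval, "configured"))


# ---------------------------------------------------------------------------
# rendering

def fpol_lut(n: int = 256) -> np.ndarray:
    """Monotone 256-entry pseudo-color LUT, black at the low end, red at the top.

    Returns an (n, 3) uint8 array.  The hue ordering (black, violet, blue,
    cyan, green, yellow, orange, red) mimics the nuclear-medicine style maps
    used for quantitative intensity display.
    """
    stops = [
        (0.00, "#000000"),
        (0.15, "#3b0f70"),
        (0.30, "#2040c0"),
        (0.45, "#00b0b0"),
        (0.60, "#00c040"),
        (0.75, "#d0d000"),
        (0.88, "#ff8000"),
        (1.00, "#ff0000"),
    ]
    cmap = LinearSegmentedColormap.from_list("fpol", stops, N=n)
    return (cmap(np.linspace(0, 1, n))[:, :3] * 255).round().astype(np.uint8)


def _render_with_lut(values, valid, lo, hi, lut):
    if not lo < hi:
        raise ValueError(f"require range_lo < range_hi, got ({lo}, {hi})")
    idx = np.clip((np.nan_to_num(values, nan=lo) - lo) / (hi - lo), 0.0, 1.0)
    idx = (idx * (len(lut) - 1)).round().astype(int)
    rgb = lut[idx]
    rgb[~valid] = 0  # invalid pixels rendered black
    return rgb


def render_fpol(
    fmap: FpolMap,
    range_lo: float = FPOL_RENDER_RANGE[0],
    range_hi: float = FPOL_RENDER_RANGE[1],
    lut: np.ndarray | None = None,
) -> np.ndarray:
    """Pseudo-color RGB rendering of an Fpol map.

    Values are clamped to ``[range_lo, range_hi]`` and mapped through the
    LUT; invalid pixels are black.  Defaults reproduce the 0-0.34 display
    range with Fpol = 0 black and Fpol = 0.34 red.
    """
    if lut is None:
        lut = fpol_lut()
    return _render_with_lut(fmap.fpol, fmap.valid_mask, range_lo, range_hi, lut)


# ---------------------------------------------------------------------------
# calibration

def calibrate_g(
    reference_pair: PolarizedImagePair,
    rule: ThresholdRule = ThresholdRule(),
    known_fpol: float = 0.0,
    min_valid_pixels: int = 100,
) -> GFactor:
    """Estimate the G-factor from a homogeneous reference of known Fpol.

    For a reference whose true polarization is ``P0`` (0 for a freely
    rotating dye in non-viscous solvent), the G that makes the mean-intensity
    Fpol equal ``P0`` is::

        G = mean(I_co) * (1 - P0) / (mean(I_cross) * (1 + P0))

    reducing to ``mean(I_co)/mean(I_cross)`` at ``P0 = 0``.
    """
    if not -1.0 < known_fpol < 1.0:
        raise ValueError("known_fpol must be in (-1, 1)")
    valid = apply_threshold(reference_pair, rule)
    n_valid = int(valid.sum())
    if n_valid < min_valid_pixels:
        raise ValueError(
            f"only {n_valid} valid reference pixels (< {min_valid_pixels}); "
            "G estimate would be unstable"
        )
    mean_co = float(reference_pair.co[valid].mean())
    mean_cross = float(reference_pair.cross[valid].mean())
    if mean_cross == 0:
        raise ZeroDivisionError("mean cross-polarized intensity is zero")
    g = mean_co * (1.0 - known_fpol) / (mean_cross * (1.0 + known_fpol))
    if g <= 0:
        raise ValueError(f"calibration produced non-positive G = {g}")
    return GFactor(value=g, source="calibrated")
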