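"""Sensing-film optics: tilt-corrected thickness, masked mean gray value,
and gray-value response time series from image stacks.

The microscope stage holds the cut film at a tilt (default 75 deg from
horizontal), so the thickness read along the Z axis overestimates the path
through the film; the corrected value is acquired / cos(90 - tilt), angles in
degrees.  Optically-active-area quantification averages pixel gray values
over a circular mask (pixel-center-in-circle rule).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import spearmanr

from .synthetic import SignalTrace

__all__ = [
    "ThicknessMeasurement",
    "CircularMask",
    "MaskedImage",
    "corrected_thickness",
    "mean_gray_value",
    "optical_response_timeseries",
    "baseline_vs_thickness_trend",
    "TrendSummary",
]

DEFAULT_TILT_DEG = 75.0


def corrected_thickness(acquired_um: float, tilt_deg: float = DEFAULT_TILT_DEG) -> float:
    """Tilt-corrected film thickness: acquired / cos(90 - tilt), degrees."""
    if acquired_um < 0:
        raise ValueError("acquired_um must be >= 0")
    if not 0 < tilt_deg <= 90:
        raise ValueError("tilt_deg must lie in (0, 90]")
    return acquired_um / np.cos(np.deg2rad(90.0 - tilt_deg))


@dataclass(frozen=True)
class ThicknessMeasurement:
    acquired_um: float
    tilt_deg: float = DEFAULT_TILT_DEG

    @property
    def measured_um(self) -> float:
        return corrected_thickness(self.acquired_um, self.tilt_deg)


@dataclass(frozen=True)
class CircularMask:
    """Circle in pixel coordinates; membership by pixel-center-in-circle."""

    center_row: float
    center_col: float
    radius_px: float

    def membership(self, shape: tuple[int, int]) -> np.ndarray:
        rows, cols = np.ogrid[: shape[0], : shape[1]]
        dist2 = (rows - self.center_row) ** 2 + (cols - self.center_col) ** 2
        return dist2 <= self.radius_px**2


@dataclass
class MaskedImage:
    pixels: np.ndarray  # 2-D grayscale
    mask: CircularMask
    pixel_scale_um: float = 1.0  # um per pixel

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim == 3:
            # unweighted channel mean for color inputs
            self.pixels = self.pixels.mean(axis=2)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D grayscale (or HxWxC color) array")
        m = self.mask
        h, w = self.pixels.shape
        if (
            m.center_row - m.radius_px < -0.5
            or m.center_col - m.radius_px < -0.5
            or m.center_row + m.radius_px > h - 0.5
            or m.center_col + m.radius_px > w - 0.5
        ):
            raise ValueError("mask extends beyond image bounds")


def mean_gray_value(image: MaskedImage) -> float:
    """Mean pixel intensity over the circular mask; outside pixels excluded."""
    member = image.mask.membership(image.pixels.shape)
    if not member.any():
        raise ValueError("mask contains no pixel centers")
    return float(image.pixels[member].mean())


def optical_response_timeseries(
    stack: Sequence[MaskedImage],
    frame_rate_hz: float,
    label: str = "",
    thickness_um: float = 0.0,
) -> SignalTrace:
    """Per-frame masked mean gray value, timestamped at ``frame_rate_hz``.

    The result is an ordinary :class:`SignalTrace`, so the preprocessing and
    feature stages apply to image-derived responses unchanged.
    """
    if frame_rate_hz <= 0:
        raise ValueError("frame_rate_hz must be positive")
    stack = list(stack)
    if not stack:
        raise ValueError("empty image stack")
    shape0, mask0 = stack[0].pixels.shape, stack[0].mask
    for frame in stack[1:]:
        if frame.pixels.shape != shape0 or frame.mask != mask0:
            raise ValueError("all frames must share image shape and mask geometry")
    values = np.array([mean_gray_value(frame) for frame in stack])
    return SignalTrace(
        values=values,
        sampling_hz=frame_rate_hz,
        voc=label,
        thickness_um=thickness_um,
        replicate_id=1,
        seed=0,
    )


@dataclass(frozen=True)
class TrendSummary:
    direction: int  # +1 increasing, -1 decreasing, 0 flat/mixed
    rank_correlation: float
    p_value: float


def baseline_vs_thickness_trend(
    pairs: Sequence[tuple[float, float]],
) -> TrendSummary:
    """Monotonic-trend direction and Spearman rank correlation of
    (thickness, quantity) pairs — used to check baseline falls / active area
    grows with thickness."""
    pairs = list(pairs)
    if len(pairs) < 3:
        raise ValueError("need at least 3 (thickness, value) pairs")
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    rho, p = spearmanr(x, y)
    rho = float(rho)
    direction = 0 if np.isnan(rho) or rho == 0 else int(np.sign(rho))
    return TrendSummary(direction=direction, rank_correlation=rho, p_value=float(p))
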