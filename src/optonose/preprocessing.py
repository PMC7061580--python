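"""Trace smoothing and exposure/recovery cycle segmentation.

Traces are first smoothed with a normalized sliding-window filter (default
window: 100 points) and then cut into fixed-length cycles; each cycle is
treated independently downstream.  Segmentation is schedule-clocked (slice at
multiples of the cycle length), not event-driven, because acquisition is
pump-clocked.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .synthetic import AssaySchedule, SignalTrace

__all__ = ["SmoothConfig", "CycleWindow", "smooth_trace", "segment_cycles", "estimate_baseline"]

logger = logging.getLogger(__name__)

#: Pre-exposure span used for the default baseline estimate, in seconds.
BASELINE_WINDOW_S = 0.5


@dataclass(frozen=True)
class SmoothConfig:
    window_points: int = 100
    window_shape: str = "hanning"  # or "rectangular"
    edge_mode: str = "reflect"

    def __post_init__(self) -> None:
        if self.window_points < 1:
            raise ValueError("window_points must be >= 1")
        if self.window_shape not in ("hanning", "rectangular"):
            raise ValueError(f"unknown window_shape {self.window_shape!r}")
        if self.edge_mode != "reflect":
            raise ValueError(f"unsupported edge_mode {self.edge_mode!r}")

    def kernel(self) -> np.ndarray:
        """Unit-sum smoothing kernel of ``window_points`` taps.

        The hanning kernel drops the zero endpoints of the raw Hann window
        (np.hanning(w + 2)[1:-1]) so every tap is strictly positive for any
        window size >= 1.
        """
        w = self.window_points
        if self.window_shape == "rectangular":
            kernel = np.ones(w)
        else:
            kernel = np.hanning(w + 2)[1:-1]
        return kernel / kernel.sum()


@dataclass
class CycleWindow:
    """One exposure/recovery cycle cut from a parent trace."""

    values: np.ndarray
    onset_index: int
    baseline: float
    voc: str
    thickness_um: float
    cycle_index: int  # 1-based
    replicate_id: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)


def smooth_values(values: np.ndarray, cfg: SmoothConfig) -> np.ndarray:
    """Normalized window convolution with reflective padding; length-preserving."""
    values = np.asarray(values, dtype=float)
    w = cfg.window_points
    if values.size < w:
        raise ValueError(
            f"trace of {values.size} samples is shorter than the smoothing window ({w})"
        )
    if w == 1:
        return values.copy()
    pad_left, pad_right = (w - 1) // 2, w // 2
    padded = np.pad(values, (pad_left, pad_right), mode="reflect")
    return np.convolve(padded, cfg.kernel(), mode="valid")


def smooth_trace(trace: SignalTrace, cfg: SmoothConfig | None = None) -> SignalTrace:
    """Return a new trace with smoothed values; metadata is carried over."""
    cfg = cfg or SmoothConfig()
    return replace(trace, values=smooth_values(trace.values, cfg))


def estimate_baseline(values: np.ndarray, n_pre: int) -> float:
    """Mean of the first ``n_pre`` samples (the pre-response region)."""
    values = np.asarray(values, dtype=float)
    if not 1 <= n_pre <= values.size:
        raise ValueError(f"n_pre={n_pre} out of range [1, {values.size}]")
    return float(values[:n_pre].mean())


def default_n_pre(schedule: AssaySchedule) -> int:
    return max(1, int(round(BASELINE_WINDOW_S * schedule.sampling_hz)))


def segment_cycles(
    trace: SignalTrace,
    schedule: AssaySchedule,
    n_pre: int | None = None,
) -> list[CycleWindow]:
    """Cut a trace into contiguous, non-overlapping cycles in temporal order.

    A trailing partial cycle is dropped with a logged warning.  Each window's
    baseline is the mean of its first ``n_pre`` samples (default: the first
    0.5 s of the cycle).
    """
    n = schedule.cycle_samples
    if len(trace) < n:
        raise ValueError(f"trace of {len(trace)} samples is shorter than one cycle ({n})")
    n_full, remainder = divmod(len(trace), n)
    if remainder:
        logger.warning(
            "trace length %d is not a multiple of cycle_samples=%d; "
            "dropping %d trailing samples",
            len(trace),
            n,
            remainder,
        )
    if n_pre is None:
        n_pre = default_n_pre(schedule)
    windows = []
    for k in range(n_full):
        values = trace.values[k * n : (k + 1) * n]
        windows.append(
            CycleWindow(
                values=values,
                onset_index=k * n,
                baseline=estimate_baseline(values, n_pre),
                voc=trace.voc,
                thickness_um=trace.thickness_um,
                cycle_index=k + 1,
                replicate_id=trace.replicate_id,
            )
        )
    return windows
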