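"""Transmigration-ratio time series and steady-state regime detection.

The per-frame transmigration ratio compares transmigrated-class pixels to
luminal-class pixels, in bulk, over the detections that survived the
noise-area filter: r = T / (T + L). The fraction form is bounded in [0,1];
the alternative odds form T/L is available via ``denominator="luminal"``.
A typical stimulated recording ramps from no activity through a sensing
phase to a plateau; the plateau ("steady state") is found as the longest
suffix over which a rolling least-squares slope of the ratio stays flat,
and its mean is the reported transmigration ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detection import Detection


@dataclass
class TransmigrationSeries:
    """Per-frame transmigration ratio with its steady-state window."""

    ratio: np.ndarray            # per-frame, NaN where no PMN pixels
    times_s: np.ndarray
    steady_state_window: tuple[int, int]   # [start_frame, end_frame] inclusive
    steady_state_mean: float

    def to_frame(self) -> pd.DataFrame:
        lo, hi = self.steady_state_window
        frames = np.arange(len(self.ratio))
        return pd.DataFrame({
            "frame": frames,
            "frame_1based": frames + 1,
            "time_s": self.times_s,
            "ratio": self.ratio,
            "in_steady_state": (frames >= lo) & (frames <= hi),
        })


def transmigration_ratio(detections: list[Detection], denominator: str = "total") -> float:
    """Bulk transmigration ratio of one frame's retained detections.

    Returns NaN when the frame has no PMN pixels (undefined, not zero).
    ``denominator="total"`` gives T/(T+L); ``"luminal"`` gives T/L.
    """
    T = sum(d.transmigrated_px for d in detections)
    L = sum(d.luminal_px for d in detections)
    if T + L == 0:
        return float("nan")
    if denominator == "total":
        return T / (T + L)
    if denominator == "luminal":
        return float("inf") if L == 0 else T / L
    raise ValueError(f"unknown denominator {denominator!r}")


def ratio_series(
    detections_by_frame: dict[int, list[Detection]],
    n_frames: int,
    frame_interval_s: float = 4.0,
    window_w: int = 30,
    slope_eps: float = 1e-3,
    denominator: str = "total",
) -> TransmigrationSeries:
    """Assemble the per-frame ratio series and locate its steady state."""
    r = np.full(n_frames, np.nan)
    for frame, dets in detections_by_frame.items():
        r[frame] = transmigration_ratio(dets, denominator=denominator)
    lo, hi = find_steady_state(r, window_w=window_w, slope_eps=slope_eps)
    window_vals = r[lo:hi + 1]
    mean = float(np.nanmean(window_vals)) if np.isfinite(window_vals).any() else float("nan")
    return TransmigrationSeries(
        ratio=r,
        times_s=np.arange(n_frames) * frame_interval_s,
        steady_state_window=(lo, hi),
        steady_state_mean=mean,
    )


def find_steady_state(series: np.ndarray, window_w: int = 30, slope_eps: float = 1e-3) -> tuple[int, int]:
    """Find the longest flat suffix of a ratio series.

    The series is scanned in rolling windows of ``window_w`` frames; a
    window is flat when the magnitude of its least-squares slope is below
    ``slope_eps`` (per frame). The steady state is the longest suffix all
    of whose windows are flat. If no suffix qualifies, the last half of
    the series is returned with a warning.
    """
    series = np.asarray(series, dtype=np.float64)
    n = len(series)
    if n <= window_w:
        raise ValueError(f"series length {n} must exceed window_w {window_w}")
    x = np.arange(window_w) - (window_w - 1) / 2.0
    denom = float((x**2).sum())
    # slope of the window starting at frame i; NaN-windows count as flat
    flat = np.ones(n - window_w + 1, dtype=bool)
    for i in range(n - window_w + 1):
        w = series[i:i + window_w]
        good = np.isfinite(w)
        if good.sum() >= 2:
            xi = x[good] - x[good].mean()
            d = float((xi**2).sum())
            slope = float((xi * (w[good] - w[good].mean())).sum()) / d if d > 0 else 0.0
        else:
            slope = 0.0
        flat[i] = abs(slope) < slope_eps
    del denom
    # longest suffix of windows that are all flat
    first_bad = -1
    for i in range(len(flat) - 1, -1, -1):
        if not flat[i]:
            first_bad = i
            break
    if first_bad == len(flat) - 1:
        warnings.warn("no steady-state regime found; falling back to the last half of the series")
        return n // 2, n - 1
    start = first_bad + 1  # first window index in the flat suffix
    return start, n - 1
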