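"""Video input/output and standardization.

Raw phase-contrast recordings arrive as 16-bit 2048x2048 TIFF stacks at
0.25 Hz (4 s frame interval). Before segmentation they are standardized:
converted to 8-bit, downscaled by bilinear interpolation, and per-frame
histogram equalized so brightness/contrast drift within and across videos
does not reach the pixel classifier. Stacks are also split into contiguous
frame chunks sized to the worker count for parallel segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import tifffile
from skimage import exposure
from skimage.transform import resize


@dataclass
class VideoStack:
    """An ordered grayscale time-lapse.

    Parameters
    ----------
    frames
        Array of shape (n_frames, height, width), dtype uint8 or uint16.
    frame_interval_s
        Seconds between consecutive frames (default 4.0, i.e. 0.25 Hz).
    pixel_size_um
        Optional physical pixel size in micrometers.
    """

    frames: np.ndarray
    frame_interval_s: float = 4.0
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(
                f"expected (n_frames, height, width) grayscale stack, got shape {self.frames.shape}"
            )
        if self.frames.shape[0] == 0:
            raise ValueError("empty stack")
        if self.frames.dtype not in (np.uint8, np.uint16):
            raise ValueError(f"expected uint8 or uint16 frames, got {self.frames.dtype}")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]

    @property
    def bit_depth(self) -> int:
        return 8 if self.frames.dtype == np.uint8 else 16

    @property
    def times_s(self) -> np.ndarray:
        """Acquisition time of each frame in seconds, starting at 0."""
        return np.arange(self.n_frames) * self.frame_interval_s


@dataclass
class SubStackPlan:
    """Contiguous, non-overlapping frame intervals covering a stack."""

    chunk_boundaries: list[tuple[int, int]] = field(default_factory=list)
    chunk_size: int = 0

    def __post_init__(self) -> None:
        prev_end = 0
        for start, end in self.chunk_boundaries:
            if start != prev_end or end <= start:
                raise ValueError("chunks must be contiguous, non-overlapping and non-empty")
            prev_end = end

    @property
    def n_frames(self) -> int:
        return self.chunk_boundaries[-1][1] if self.chunk_boundaries else 0


def read_stack(path, frame_interval_s: float = 4.0, pixel_size_um: float | None = None) -> VideoStack:
    """Read a grayscale multi-page TIFF into a :class:`VideoStack`."""
    frames = tifffile.imread(path)
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise ValueError(f"non-grayscale or unsupported TIFF layout: shape {frames.shape}")
    return VideoStack(frames, frame_interval_s=frame_interval_s, pixel_size_um=pixel_size_um)


def write_stack(stack: VideoStack, path) -> None:
    """Write a stack as an uncompressed grayscale multi-page TIFF."""
    tifffile.imwrite(path, stack.frames, photometric="minisblack")


def standardize(stack: VideoStack, target_size: int = 1024, target_bits: int = 8) -> VideoStack:
    """Bit-depth reduce and downscale a stack.

    16-bit input is mapped to 8-bit by a linear min-max rescale over the
    *whole stack's* intensity range (not per frame), so slow temporal
    intensity trends survive until equalization. Spatial downscaling uses
    bilinear interpolation. A zero-range stack maps to 0.
    """
    if target_bits != 8:
        raise ValueError("only 8-bit output is supported")
    if target_size <= 0:
        raise ValueError("target_size must be positive")
    frames = stack.frames.astype(np.float64)
    if stack.bit_depth == 16:
        lo, hi = frames.min(), frames.max()
        frames = np.zeros_like(frames) if hi == lo else (frames - lo) * (255.0 / (hi - lo))
    if target_size != stack.height or target_size != stack.width:
        out = np.empty((stack.n_frames, target_size, target_size), dtype=np.float64)
        for i, f in enumerate(frames):
            # order=1 == bilinear; anti_aliasing pre-blurs on downscale
            out[i] = resize(f, (target_size, target_size), order=1,
                            anti_aliasing=False, preserve_range=True)
        frames = out
    frames = np.clip(np.rint(frames), 0, 255).astype(np.uint8)
    return replace(stack, frames=frames)


def equalize(stack: VideoStack, scope: str = "frame") -> VideoStack:
    """Histogram-equalize an 8-bit stack over 256 bins.

    ``scope='frame'`` (default) equalizes each frame independently,
    stabilizing brightness through the video; ``scope='stack'`` uses one
    cumulative histogram for the whole stack.
    """
    if stack.bit_depth != 8:
        raise ValueError("equalize expects an 8-bit stack (run standardize first)")
    if scope not in ("frame", "stack"):
        raise ValueError(f"unknown scope {scope!r}")
    if scope == "stack":
        eq = exposure.equalize_hist(stack.frames, nbins=256)
        frames = np.clip(np.rint(eq * 255.0), 0, 255).astype(np.uint8)
    else:
        frames = np.empty_like(stack.frames)
        for i, f in enumerate(stack.frames):
            eq = exposure.equalize_hist(f, nbins=256)
            frames[i] = np.clip(np.rint(eq * 255.0), 0, 255).astype(np.uint8)
    return replace(stack, frames=frames)


def plan_substacks(n_frames: int, n_workers: int) -> SubStackPlan:
    """Split ``n_frames`` into contiguous chunks of ``n_workers`` frames.

    Chunk size matches the worker count (a 450-frame video split for 18
    workers yields 25 chunks of 18); the final chunk may be shorter.
    """
    if n_frames < 1 or n_workers < 1:
        raise ValueError("n_frames and n_workers must be >= 1")
    bounds = [(start, min(start + n_workers, n_frames)) for start in range(0, n_frames, n_workers)]
    return SubStackPlan(chunk_boundaries=bounds, chunk_size=n_workers)
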