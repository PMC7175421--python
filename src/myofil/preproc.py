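"""Raw-stack preprocessing: flat-field correction, preaveraging, median filtering.

The processing chain mirrors standard iSCAT practice: raw frames are divided
by a flat-field image (the per-pixel temporal median of a moving-stage
acquisition, containing only static illumination structure), preaveraged in
non-overlapping blocks to reduce shot noise, and temporally median-filtered
so that quasi-static structures (immobile actin, surface impurities) are
removed while transiently bound, mobile particles survive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .stack import ImageStack

__all__ = [
    "compute_flatfield",
    "flatfield_correct",
    "preaverage",
    "temporal_median_subtract",
    "MedianFilterResult",
    "last_frame_minus_median",
    "bandpass",
    "contrast_to_tracing_units",
]


def compute_flatfield(stack: ImageStack, check_positive: bool = False) -> np.ndarray:
    """Per-pixel temporal median over all frames.

    On a moving-stage acquisition this isolates the static features
    (illumination inhomogeneity, fixed-pattern noise, constant background)
    because any given sample structure occupies each pixel only transiently.
    With ``check_positive`` the result is validated for use as a divisor.
    """
    if stack.n_frames < 3:
        raise ValueError("flat-field estimation needs at least 3 frames")
    ff = np.median(stack.frames, axis=0)
    if check_positive:
        n_bad = int(np.count_nonzero(ff == 0))
        if n_bad:
            raise ValueError(f"flat field has {n_bad} zero-valued pixel(s); "
                             "cannot be used as a divisor")
    return ff


def flatfield_correct(stack: ImageStack, flatfield: np.ndarray,
                      to_contrast: bool = False) -> ImageStack:
    """Divide each frame pixelwise by the flat field.

    With ``to_contrast`` the result is additionally shifted by -1, turning
    the ratiometric image into interferometric contrast (background-divided
    signal minus one).
    """
    flatfield = np.asarray(flatfield)
    if flatfield.shape != stack.frame_shape:
        raise ValueError(f"flatfield shape {flatfield.shape} does not match "
                         f"frame shape {stack.frame_shape}")
    if np.any(flatfield == 0):
        raise ValueError("flatfield contains zero-valued pixels")
    out = stack.frames / flatfield[None, :, :]
    if to_contrast:
        out = out - 1.0
    return stack.with_frames(out, note=f"flatfield_correct(to_contrast={to_contrast})")


def preaverage(stack: ImageStack, factor: int) -> ImageStack:
    """Average non-overlapping blocks of ``factor`` frames.

    The frame interval is multiplied by ``factor`` (e.g. 25 Hz preaveraged
    by 5 gives an effective 5 Hz, dt = 0.2 s); a trailing incomplete block
    is dropped.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor > stack.n_frames:
        raise ValueError(f"factor {factor} exceeds the {stack.n_frames}-frame stack")
    if factor == 1:
        return stack.with_frames(stack.frames.copy(), note="preaverage(1)")
    n_blocks = stack.n_frames // factor
    trimmed = stack.frames[:n_blocks * factor]
    out = trimmed.reshape(n_blocks, factor, *stack.frame_shape).mean(axis=1)
    return stack.with_frames(out, dt_s=stack.dt_s * factor,
                             note=f"preaverage({factor})")


@dataclass
class MedianFilterResult:
    """Median-filtered stack plus the subtracted median image(s).

    ``medians`` has one median frame per (non-overlapping) window;
    ``window_frames`` records the window length.  ``reconstruct`` returns
    the exact input (filtered + median, pixelwise).
    """

    filtered: ImageStack
    medians: np.ndarray          # (n_windows, H, W)
    window_frames: int

    @property
    def median_image(self) -> np.ndarray:
        """The (first) median frame; for whole-sequence mode, the global median."""
        return self.medians[0]

    def reconstruct(self) -> np.ndarray:
        out = self.filtered.frames.copy()
        n = out.shape[0]
        for w, med in enumerate(self.medians):
            lo = w * self.window_frames
            hi = min(lo + self.window_frames, n)
            out[lo:hi] += med
        return out


def temporal_median_subtract(stack: ImageStack, window_frames: int | None = None,
                             mode: str = "blocks") -> MedianFilterResult:
    """Subtract the per-pixel temporal median from every frame.

    With ``window_frames=None`` (whole-sequence mode) the global per-pixel
    median is subtracted everywhere.  Otherwise the stack is split into
    non-overlapping windows of ``window_frames`` frames and each window's
    median is subtracted from that window's frames; a 50-frame window at an
    effective 5 Hz corresponds to 10 s and suppresses everything static on
    that timescale.  ``mode='rolling'`` uses a centred rolling median
    instead (O(n * window) — slower, offered for comparison).
    """
    n = stack.n_frames
    if window_frames is None:
        window_frames = n
    if window_frames < 3:
        raise ValueError("window_frames must be >= 3")
    if window_frames > n:
        raise ValueError(f"window of {window_frames} frames exceeds the "
                         f"{n}-frame stack")
    if mode == "rolling":
        half = window_frames // 2
        filt = np.empty_like(stack.frames)
        meds = np.empty_like(stack.frames)
        for f in range(n):
            lo = max(0, f - half)
            hi = min(n, lo + window_frames)
            lo = max(0, hi - window_frames)
            meds[f] = np.median(stack.frames[lo:hi], axis=0)
            filt[f] = stack.frames[f] - meds[f]
        result = MedianFilterResult(
            filtered=stack.with_frames(filt, note="temporal_median_subtract(rolling)"),
            medians=meds, window_frames=1)
        return result
    if mode != "blocks":
        raise ValueError("mode must be 'blocks' or 'rolling'")
    n_windows = int(np.ceil(n / window_frames))
    meds = np.empty((n_windows, *stack.frame_shape), dtype=stack.frames.dtype)
    filt = np.empty_like(stack.frames)
    for w in range(n_windows):
        lo = w * window_frames
        hi = min(lo + window_frames, n)
        meds[w] = np.median(stack.frames[lo:hi], axis=0)
        filt[lo:hi] = stack.frames[lo:hi] - meds[w]
    return MedianFilterResult(
        filtered=stack.with_frames(
            filt, note=f"temporal_median_subtract(window={window_frames})"),
        medians=meds, window_frames=window_frames)


def last_frame_minus_median(stack: ImageStack, segment_s: float = 10.0) -> ImageStack:
    """Per segment, subtract the segment median from the segment's last frame.

    Splits the stack into segments of ``segment_s`` seconds and returns one
    output frame per segment — the visualization used to isolate freshly
    landed filaments (structures present only at the segment end survive;
    anything quasi-static cancels).
    """
    seg_frames = max(3, int(round(segment_s / stack.dt_s)))
    n_seg = stack.n_frames // seg_frames
    if n_seg < 1:
        raise ValueError("stack shorter than one segment")
    out = np.empty((n_seg, *stack.frame_shape), dtype=stack.frames.dtype)
    for s in range(n_seg):
        lo = s * seg_frames
        hi = lo + seg_frames
        out[s] = stack.frames[hi - 1] - np.median(stack.frames[lo:hi], axis=0)
    return stack.with_frames(out, dt_s=stack.dt_s * seg_frames,
                             note=f"last_frame_minus_median(segment_s={segment_s})")


def bandpass(frame: np.ndarray, low_px: float = 3.0, high_px: float = 20.0) -> np.ndarray:
    """Difference-of-Gaussians bandpass (smooth at ``low_px``, remove structure
    larger than ``high_px``), as used before filament backbone tracing."""
    frame = np.asarray(frame, dtype=float)
    return gaussian_filter(frame, low_px) - gaussian_filter(frame, high_px)


def contrast_to_tracing_units(x: np.ndarray) -> np.ndarray:
    """Map contrast to the integer intensity code f(x) = 1000*(-x) + 1000.

    This is the exact mapping applied before 8-bit conversion for backbone
    tracing; analysis in this package stays in float, the utility exists for
    parity with that workflow.
    """
    return np.rint(1000.0 * (-np.asarray(x, dtype=float)) + 1000.0).astype(np.int64)
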