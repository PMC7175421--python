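"""Image-stack container and TIFF/CSV round-tripping.

The pipeline's raw input is a time-ordered stack of interferometric contrast
frames.  Contrast here is the normalized, background-divided pixel signal
minus one; dark particles (actin and myosin filaments) have contrast < 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["ImageStack"]


@dataclass
class ImageStack:
    """A (frame, row, col) stack of contrast values with physical calibration.

    Parameters
    ----------
    frames
        3-D float array, shape ``(n_frames, height, width)``.
    dt_s
        Frame interval in seconds (the *effective* interval after any
        preaveraging).
    pixel_size_nm
        Lateral pixel size in nanometres.
    meta
        Free-form provenance record; every preprocessing operation appends
        a description of itself here.
    """

    frames: np.ndarray
    dt_s: float
    pixel_size_nm: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a 3-D array with at least one frame")
        if not self.dt_s > 0:
            raise ValueError("dt_s must be positive")
        if not self.pixel_size_nm > 0:
            raise ValueError("pixel_size_nm must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def pixel_size_um(self) -> float:
        return self.pixel_size_nm / 1000.0

    @property
    def fov_um(self) -> tuple[float, float]:
        """Field of view (width, height) in micrometres."""
        h, w = self.frame_shape
        return (w * self.pixel_size_um, h * self.pixel_size_um)

    def with_frames(self, frames: np.ndarray, *, dt_s: float | None = None,
                    note: str | None = None) -> "ImageStack":
        """Copy of this stack with new frames and an optional metadata note."""
        meta = dict(self.meta)
        if note:
            meta.setdefault("history", [])
            meta["history"] = list(meta["history"]) + [note]
        return ImageStack(frames=frames, dt_s=self.dt_s if dt_s is None else dt_s,
                          pixel_size_nm=self.pixel_size_nm, meta=meta)

    # ------------------------------------------------------------------ I/O
    def save_tiff(self, path: str | Path) -> None:
        """Write as a multi-page 32-bit float TIFF, metadata in the description tag."""
        desc = json.dumps({"dt_s": self.dt_s, "pixel_size_nm": self.pixel_size_nm,
                           "meta": _jsonable(self.meta)})
        tifffile.imwrite(str(path), self.frames.astype(np.float32),
                         description=desc, photometric="minisblack")

    @classmethod
    def from_tiff(cls, path: str | Path, dt_s: float | None = None,
                  pixel_size_nm: float | None = None) -> "ImageStack":
        """Read a multi-page TIFF; calibration from the description tag unless given."""
        with tifffile.TiffFile(str(path)) as tif:
            frames = tif.asarray()
            desc = tif.pages[0].description
        if frames.ndim == 2:
            frames = frames[None]
        meta: dict = {}
        try:
            info = json.loads(desc)
            dt_s = dt_s if dt_s is not None else info.get("dt_s")
            pixel_size_nm = (pixel_size_nm if pixel_size_nm is not None
                             else info.get("pixel_size_nm"))
            meta = info.get("meta", {})
        except (json.JSONDecodeError, TypeError):
            pass
        if dt_s is None or pixel_size_nm is None:
            raise ValueError("dt_s and pixel_size_nm not found in TIFF metadata; "
                             "pass them explicitly")
        return cls(frames=frames, dt_s=float(dt_s),
                   pixel_size_nm=float(pixel_size_nm), meta=meta)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
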