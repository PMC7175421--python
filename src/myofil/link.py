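"""Frame-to-frame linking of detections into single-particle tracks.

Tracks are assembled by gated nearest-neighbour assignment: a detection may
continue a track only if the spatial displacement, the axial orientation
change and the area ratio between the two detections all pass their gates.
Assignments within each frame pair are resolved greedily by ascending
displacement (each detection used once); short detection dropouts are
bridged up to a configurable number of gap frames.  A globally optimal
(Hungarian) assignment is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .detect import Detection

__all__ = ["Track", "link_detections", "extract_dwell_times", "tracks_to_dataframe"]


def axial_angle_diff(t1: float, t2: float) -> float:
    """Smallest difference between two axial orientations, in [0, pi/2]."""
    d = abs(t1 - t2) % np.pi
    return min(d, np.pi - d)


@dataclass
class Track:
    """Time-ordered detections of one particle.

    ``dwell_s`` spans first to last frame inclusive (gap frames count as
    bound — the particle was present, merely missed by detection).
    ``censored`` flags tracks touching the first or last recorded frame,
    whose true dwell extends beyond the recording window.
    """

    id: int
    detections: list = field(default_factory=list)
    dt_s: float = 1.0
    censored: bool = False

    @property
    def frames(self) -> np.ndarray:
        return np.array([d.frame for d in self.detections])

    @property
    def xy_um(self) -> np.ndarray:
        return np.array([[d.x_um, d.y_um] for d in self.detections])

    @property
    def theta_rad(self) -> np.ndarray:
        return np.array([d.theta_rad for d in self.detections])

    @property
    def n_detections(self) -> int:
        return len(self.detections)

    @property
    def t_start_s(self) -> float:
        return self.detections[0].frame * self.dt_s

    @property
    def t_end_s(self) -> float:
        return self.detections[-1].frame * self.dt_s

    @property
    def dwell_s(self) -> float:
        return self.t_end_s - self.t_start_s + self.dt_s


def _admissible(prev: Detection, new: Detection, max_disp_um: float,
                max_dtheta_rad: float, area_ratio_max: float) -> float | None:
    """Displacement if the pair passes all gates, else None."""
    disp = float(np.hypot(new.x_um - prev.x_um, new.y_um - prev.y_um))
    if disp > max_disp_um:
        return None
    if axial_angle_diff(prev.theta_rad, new.theta_rad) > max_dtheta_rad:
        return None
    lo, hi = sorted((prev.area_px, new.area_px))
    if lo == 0 or hi / lo > area_ratio_max:
        return None
    return disp


def link_detections(detections, dt_s: float, n_frames: int | None = None,
                    max_disp_um: float = 0.5,
                    max_dtheta_rad: float = np.pi / 4,
                    area_ratio_max: float = 2.0,
                    max_gap_frames: int = 1,
                    method: str = "greedy") -> list[Track]:
    """Assemble detections into tracks.

    ``detections`` is a flat list (sorted or not; they are grouped by frame
    internally).  ``n_frames`` is the recording length, used to flag
    censored tracks; defaults to ``max(frame) + 1``.  The displacement gate
    is per frame *pair* — a bridged gap does not widen it.
    """
    dets = sorted(detections, key=lambda d: d.frame)
    if not dets:
        return []
    if n_frames is None:
        n_frames = dets[-1].frame + 1
    by_frame: dict[int, list[Detection]] = {}
    for d in dets:
        by_frame.setdefault(d.frame, []).append(d)

    tracks: list[Track] = []
    active: list[Track] = []
    for f in sorted(by_frame):
        frame_dets = by_frame[f]
        candidates = [t for t in active
                      if f - t.detections[-1].frame <= max_gap_frames + 1
                      and t.detections[-1].frame < f]
        pairs = []
        for ti, t in enumerate(candidates):
            for di, d in enumerate(frame_dets):
                disp = _admissible(t.detections[-1], d, max_disp_um,
                                   max_dtheta_rad, area_ratio_max)
                if disp is not None:
                    pairs.append((disp, ti, di))
        used_t: set[int] = set()
        used_d: set[int] = set()
        if method == "hungarian" and pairs:
            cost = np.full((len(candidates), len(frame_dets)), 1e9)
            for disp, ti, di in pairs:
                cost[ti, di] = disp
            rows, cols = linear_sum_assignment(cost)
            for ti, di in zip(rows, cols):
                if cost[ti, di] < 1e9:
                    candidates[ti].detections.append(frame_dets[di])
                    used_t.add(ti)
                    used_d.add(di)
        else:
            for disp, ti, di in sorted(pairs, key=lambda p: p[0]):
                if ti in used_t or di in used_d:
                    continue
                candidates[ti].detections.append(frame_dets[di])
                used_t.add(ti)
                used_d.add(di)
        for di, d in enumerate(frame_dets):
            if di not in used_d:
                t = Track(id=len(tracks), dt_s=dt_s, detections=[d])
                tracks.append(t)
                active.append(t)
        active = [t for t in active
                  if f - t.detections[-1].frame <= max_gap_frames]
    for t in tracks:
        t.censored = (t.detections[0].frame == 0
                      or t.detections[-1].frame == n_frames - 1)
    return tracks


def extract_dwell_times(tracks, drop_censored: bool = True):
    """Dwell times (seconds) of tracks from one recording window.

    A track's dwell spans its first to last frame plus one frame interval.
    With ``drop_censored`` (the default) tracks touching the recording
    boundary are excluded — only complete binding-unbinding cycles within
    the window are counted, which biases the slow dwell components downward
    in a way the truncation-aware fitting can account for.  Otherwise all
    dwells are returned together with their censor flags.
    """
    if drop_censored:
        return [t.dwell_s for t in tracks if not t.censored]
    return [(t.dwell_s, t.censored) for t in tracks]


def tracks_to_dataframe(tracks) -> pd.DataFrame:
    rows = []
    for t in tracks:
        for d in t.detections:
            rows.append((t.id, d.frame, d.x_um, d.y_um, d.theta_rad,
                         d.area_px, d.mean_contrast, t.censored))
    return pd.DataFrame(rows, columns=["track_id", "frame", "x_um", "y_um",
                                       "theta_rad", "area_px",
                                       "mean_contrast", "censored"])
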