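"""Shared fixtures: a rendered high-SNR benchmark movie with ground truth.

The benchmark is the default detection/tracking scene: ten myosin II
filaments (635-nm contrast, SNR ~ 17) bound for the whole recording and
moving diffusively, rendered with static roughness and fixed-pattern fields
plus shot noise, then temporally median-subtracted before detection.
"""

from __future__ import annotations

from types import SimpleNamespace

import numpy as np
import pytest

from myofil import detect as mdetect
from myofil import link as mlink
from myofil.preproc import temporal_median_subtract
from myofil.simulate import (GroundTruth, OpticsConfig, ParticleTruth,
                             STATE_RANDOM, render_movie)


def make_brownian_myosin(pid: int, rng: np.random.Generator, n_frames: int,
                         dt_s: float, fov_um: tuple[float, float],
                         D: float = 0.005, margin_um: float = 1.2,
                         contrast: float = -0.017,
                         start_xy: tuple[float, float] | None = None
                         ) -> ParticleTruth:
    """One always-bound myosin filament performing 2-D Brownian motion."""
    W, H = fov_um
    x = np.empty(n_frames)
    y = np.empty(n_frames)
    if start_xy is None:
        x[0] = rng.uniform(margin_um, W - margin_um)
        y[0] = rng.uniform(margin_um, H - margin_um)
    else:
        x[0], y[0] = start_xy
    sd = np.sqrt(2 * D * dt_s)
    x[1:] = x[0] + np.cumsum(rng.normal(0, sd, n_frames - 1))
    y[1:] = y[0] + np.cumsum(rng.normal(0, sd, n_frames - 1))
    theta = np.mod(rng.uniform(0, np.pi)
                   + np.cumsum(rng.normal(0, 0.05, n_frames)), np.pi)
    return ParticleTruth(
        id=pid, species="myosin", birth_frame=0, death_frame=n_frames - 1,
        x_um=x, y_um=y, theta_rad=theta,
        state=np.full(n_frames, STATE_RANDOM, dtype=object),
        length_um=0.52, contrast=contrast,
        dwell_s=n_frames * dt_s, censored=True)


@pytest.fixture(scope="session")
def benchmark_run():
    """Simulate, render, median-subtract, detect and link the benchmark scene."""
    rng = np.random.default_rng(42)
    optics = OpticsConfig(fov_px=(256, 256))
    n_frames = 100
    dt = 0.2
    # isolated filaments (the regime the tracking method targets): jittered
    # grid starts keep particles from crossing within one PSF width
    W, H = optics.fov_um
    grid = [(W * (0.5 + i) / 4 + rng.uniform(-0.3, 0.3),
             H * (0.5 + j) / 3 + rng.uniform(-0.3, 0.3))
            for i in range(4) for j in range(3)][:10]
    particles = [make_brownian_myosin(i, rng, n_frames, dt, optics.fov_um,
                                      start_xy=grid[i])
                 for i in range(10)]
    truth = GroundTruth(particles=particles, n_frames=n_frames, dt_s=dt,
                        fov_um=optics.fov_um)
    stack = render_movie(truth, optics, seed=42)
    filtered = temporal_median_subtract(stack).filtered
    detections = []
    for f in range(n_frames):
        detections.extend(mdetect.detect_particles(
            filtered.frames[f], pixel_size_nm=optics.pixel_size_nm,
            k_sigma=4.0, min_area_px=9, frame_index=f))
    tracks = mlink.link_detections(detections, dt_s=dt, n_frames=n_frames)
    return SimpleNamespace(truth=truth, stack=stack, filtered=filtered,
                           detections=detections, tracks=tracks,
                           segments_by_track={}, optics=optics)
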