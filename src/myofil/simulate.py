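"""Synthetic iSCAT movie generator with full ground truth.

Emulates the statistical structure of label-free recordings of membrane-bound
actin networks and myosin II filaments:

* negative-contrast rod-like actin filaments diffusing on the membrane plane,
  with length-dependent mobility and confinement of long filaments by the
  surrounding network;
* ellipsoidal myosin II filaments arriving by a Poisson process, dwelling for
  multi-exponential mixture times, and alternating random (Brownian) and
  directed (processive) motion, with orientation fluctuations modelled as an
  Ornstein-Uhlenbeck process whose stationary variance is k_B*T / K_tor;
* a Gaussian point-spread function, static glass-roughness background,
  fixed-pattern noise, and per-frame shot noise.

Every particle's true position, axial orientation and motion state is
recorded per frame, so detection, tracking, motion classification and
kinetic fitting can all be scored against ground truth.

Coordinate convention: continuous positions in micrometres with the origin at
the field-of-view corner; pixel (i, j) covers [j*px, (j+1)*px) x
[i*px, (i+1)*px) so pixel centres sit at ((j+0.5)*px, (i+0.5)*px); frame
indices are 0-based.  Orientations are axial (undirected), stored in [0, pi).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .stack import ImageStack

__all__ = [
    "BOLTZMANN_PN_NM_PER_K",
    "OpticsConfig",
    "ActinSceneConfig",
    "MyosinSceneConfig",
    "ParticleTruth",
    "GroundTruth",
    "sample_dwell_times",
    "simulate_trajectories",
    "render_movie",
    "compose_raw",
    "moving_stage_stack",
]

#: Boltzmann constant in pN nm / K (1.380649e-23 J/K = 1.380649e-2 pN nm/K).
BOLTZMANN_PN_NM_PER_K = 1.380649e-2

# Species contrast (mean, sd) per laser wavelength, from calibration on glass.
SPECIES_CONTRAST = {
    ("actin", 445): (-0.058, 0.015),
    ("actin", 635): (-0.002, 0.001),
    ("myosin", 445): (-0.120, 0.026),
    ("myosin", 635): (-0.017, 0.006),
}

_PIXEL_SIZE_NM = {445: 23.4, 635: 31.8}
_FRAME_RATE_HZ = {445: 50.0, 635: 25.0}
_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.355


@dataclass
class OpticsConfig:
    """Imaging model: geometry, PSF and noise of one iSCAT setup.

    Defaults correspond to the 635-nm laser setup (31.8 nm/px, 25 fps);
    pass ``wavelength_nm=445`` for the 445-nm setup (23.4 nm/px, 50 fps).
    ``shot_noise_sd`` is the per-pixel, per-frame contrast noise after the
    camera; the default 0.001 puts a single myosin filament (contrast
    -0.017 at 635 nm) at SNR ~ 17.
    """

    wavelength_nm: int = 635
    pixel_size_nm: float | None = None
    psf_fwhm_nm: float = 210.0
    reflectivity_r: float = 0.065
    frame_rate_hz: float | None = None
    shot_noise_sd: float = 0.001
    fixed_pattern_amplitude: float = 0.002
    roughness_amplitude: float = 0.005
    fov_px: tuple[int, int] = (256, 256)  # (height, width)

    def __post_init__(self) -> None:
        if self.wavelength_nm not in (445, 635):
            raise ValueError("wavelength_nm must be 445 or 635")
        if self.pixel_size_nm is None:
            self.pixel_size_nm = _PIXEL_SIZE_NM[self.wavelength_nm]
        if self.frame_rate_hz is None:
            self.frame_rate_hz = _FRAME_RATE_HZ[self.wavelength_nm]
        if not self.pixel_size_nm > 0:
            raise ValueError("pixel_size_nm must be positive")
        if not self.psf_fwhm_nm > 0:
            raise ValueError("psf_fwhm_nm must be positive")
        if not 0 < self.reflectivity_r < 1:
            raise ValueError("reflectivity_r must lie in (0, 1)")

    @property
    def dt_s(self) -> float:
        return 1.0 / self.frame_rate_hz

    @property
    def pixel_size_um(self) -> float:
        return self.pixel_size_nm / 1000.0

    @property
    def psf_sigma_px(self) -> float:
        return self.psf_fwhm_nm / _FWHM_TO_SIGMA / self.pixel_size_nm

    @property
    def fov_um(self) -> tuple[float, float]:
        """(width, height) in micrometres."""
        h, w = self.fov_px
        return (w * self.pixel_size_um, h * self.pixel_size_um)


@dataclass
class ActinSceneConfig:
    """Membrane-tethered actin filaments diffusing in the network plane.

    ``diffusivity_um2_s`` is the translational diffusion coefficient of a
    1-um filament; mobility scales as 1/length.  The default 0.005 um^2/s
    puts the 5-s MSD of a short free filament at ~0.1 um^2.  Filaments
    longer than ``confinement_length_um`` are confined by the surrounding
    meshwork, modelled as a harmonic trap whose stationary r.m.s. excursion
    per axis is ``confinement_radius_um``.
    """

    n_filaments: int = 10
    length_um: tuple[float, float] = (2.0, 1.5)        # (mean, sd)
    contrast: tuple[float, float] = (-0.002, 0.001)     # (mean, sd), 635 nm
    diffusivity_um2_s: float = 0.005
    confinement_length_um: float = 1.5
    confinement_radius_um: float = 0.15
    min_length_um: float = 0.2

    def __post_init__(self) -> None:
        if self.length_um[0] <= 0:
            raise ValueError("mean filament length must be positive")
        if self.diffusivity_um2_s < 0:
            raise ValueError("diffusivity must be non-negative")

    @classmethod
    def for_wavelength(cls, wavelength_nm: int, **kw) -> "ActinSceneConfig":
        kw.setdefault("contrast", SPECIES_CONTRAST[("actin", wavelength_nm)])
        return cls(**kw)


@dataclass
class MyosinSceneConfig:
    """Myosin II filaments binding to, moving on, and leaving the network.

    Dwell times are a mixture of exponentials ``dwell_mixture`` =
    [(fraction, tau_s), ...].  While bound, a filament alternates random
    (Brownian, ``D_random_um2_s``) and directed segments; each new segment
    is directed with probability ``p_directed``.  Directed runs move at a
    per-run speed drawn from ``v_directed_um_s`` along a fixed run bearing,
    while the body axis fluctuates about that bearing as an
    Ornstein-Uhlenbeck process with stationary variance
    k_B*T / ``angular_stiffness_pN_nm`` and relaxation time
    ``orientation_relax_s``.
    """

    arrival_rate_per_s: float = 1.0
    dwell_mixture: Sequence[tuple[float, float]] = (
        (0.55, 0.34), (0.35, 2.26), (0.10, 10.9))
    length_nm: tuple[float, float] = (520.0, 130.0)
    contrast: tuple[float, float] = (-0.017, 0.006)     # (mean, sd), 635 nm
    v_directed_um_s: tuple[float, float] = (0.46, 0.20)
    D_random_um2_s: float = 0.005
    p_directed: float = 0.3
    run_min_s: float = 2.0
    directed_duration_s: tuple[float, float] = (2.2, 0.8)   # (mean, sd)
    random_duration_s: tuple[float, float] = (4.0, 1.5)     # (mean, sd)
    angular_stiffness_pN_nm: float = 7.5
    orientation_relax_s: float = 1.0
    temperature_K: float = 295.15

    def __post_init__(self) -> None:
        _validate_mixture(self.dwell_mixture)
        if self.length_nm[1] < 0 or self.v_directed_um_s[1] < 0:
            raise ValueError("standard deviations must be non-negative")

    @property
    def orientation_variance_rad2(self) -> float:
        """Stationary orientation-fluctuation variance k_B*T / K_tor."""
        return (BOLTZMANN_PN_NM_PER_K * self.temperature_K
                / self.angular_stiffness_pN_nm)

    @classmethod
    def for_wavelength(cls, wavelength_nm: int, **kw) -> "MyosinSceneConfig":
        kw.setdefault("contrast", SPECIES_CONTRAST[("myosin", wavelength_nm)])
        return cls(**kw)


def _validate_mixture(mixture: Sequence[tuple[float, float]]) -> None:
    fracs = [f for f, _ in mixture]
    if abs(sum(fracs) - 1.0) > 1e-9:
        raise ValueError(f"mixture fractions must sum to 1, got {sum(fracs)!r}")
    for i, (f, tau) in enumerate(mixture):
        if tau <= 0:
            raise ValueError(f"mixture component {i} has non-positive tau={tau!r}")
        if f < 0:
            raise ValueError(f"mixture component {i} has negative fraction={f!r}")


# --------------------------------------------------------------------------
# Ground truth
# --------------------------------------------------------------------------

STATE_RANDOM = "random"
STATE_DIRECTED = "directed"


@dataclass
class ParticleTruth:
    """True per-frame record of one simulated particle.

    Arrays run from ``birth_frame`` to ``death_frame`` inclusive.
    ``dwell_s`` is the *drawn* dwell time before any clipping by the
    recording window; ``censored`` flags events clipped by the window.
    """

    id: int
    species: str                      # 'actin' | 'myosin'
    birth_frame: int
    death_frame: int
    x_um: np.ndarray
    y_um: np.ndarray
    theta_rad: np.ndarray             # axial, in [0, pi)
    state: np.ndarray                 # STATE_RANDOM / STATE_DIRECTED per frame
    length_um: float
    contrast: float
    dwell_s: float
    censored: bool
    run_lengths_um: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.death_frame < self.birth_frame:
            raise ValueError("death_frame must be >= birth_frame")

    @property
    def n_frames(self) -> int:
        return self.death_frame - self.birth_frame + 1


@dataclass
class GroundTruth:
    """All simulated particles plus the recording geometry."""

    particles: list
    n_frames: int
    dt_s: float
    fov_um: tuple[float, float]       # (width, height)

    def alive_at(self, frame: int) -> list:
        return [p for p in self.particles
                if p.birth_frame <= frame <= p.death_frame]

    def to_dataframe(self) -> pd.DataFrame:
        """One row per particle per frame: frame, id, species, x, y, theta, state."""
        rows = []
        for p in self.particles:
            for k in range(p.n_frames):
                rows.append((p.birth_frame + k, p.id, p.species,
                             p.x_um[k], p.y_um[k], p.theta_rad[k], p.state[k]))
        return pd.DataFrame(rows, columns=["frame", "id", "species", "x_um",
                                           "y_um", "theta_rad", "state"])

    def save_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


# --------------------------------------------------------------------------
# Dwell-time sampling
# --------------------------------------------------------------------------

def sample_dwell_times(mixture: Sequence[tuple[float, float]], n: int,
                       seed: int | np.random.Generator = 0) -> np.ndarray:
    """Draw ``n`` i.i.d. dwell times from an exponential mixture.

    Each draw picks a component with probability equal to its fraction and
    then draws an exponential duration with that component's time constant.
    """
    _validate_mixture(mixture)
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    fracs = np.array([f for f, _ in mixture], dtype=float)
    taus = np.array([t for _, t in mixture], dtype=float)
    comp = rng.choice(len(mixture), size=n, p=fracs / fracs.sum())
    return rng.exponential(taus[comp])


def exp_mixture_cdf(t, mixture: Sequence[tuple[float, float]]) -> np.ndarray:
    """Analytic CDF of the exponential mixture (used as an independent oracle)."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    for f, tau in mixture:
        out += f * (1.0 - np.exp(-t / tau))
    return out


# --------------------------------------------------------------------------
# Trajectory simulation
# --------------------------------------------------------------------------

def _ou_step(x, mean, relax_s, stat_var, dt, rng, size=None):
    """One exact Ornstein-Uhlenbeck update over dt."""
    decay = np.exp(-dt / relax_s)
    sd = np.sqrt(stat_var * (1.0 - decay ** 2))
    return mean + (x - mean) * decay + rng.normal(0.0, sd, size=size)


def _draw_duration(mean_sd: tuple[float, float], lo: float, rng) -> float:
    mean, sd = mean_sd
    if sd == 0:
        return max(mean, lo)
    return max(rng.normal(mean, sd), lo)


def simulate_trajectories(actin: ActinSceneConfig | None,
                          myosin: MyosinSceneConfig | None,
                          n_frames: int, dt_s: float, seed: int = 0,
                          fov_um: tuple[float, float] = (8.0, 8.0)) -> GroundTruth:
    """Simulate all particle trajectories (no rendering).

    Actin filaments perform 2-D Brownian motion with 1/length mobility
    scaling; filaments longer than the confinement cutoff relax in a
    harmonic trap instead.  Myosin filaments land as a Poisson process,
    dwell for a mixture-of-exponentials time (clipped by the recording
    window, with censoring flagged) and alternate random and directed
    motion.  An empty scene (both configs None or zero particles) yields a
    background-only ground truth.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")
    rng = np.random.default_rng(seed)
    W, H = fov_um
    particles: list[ParticleTruth] = []
    next_id = 0

    if actin is not None:
        for _ in range(actin.n_filaments):
            L = max(rng.normal(*actin.length_um), actin.min_length_um)
            contrast = min(rng.normal(*actin.contrast), -1e-6)
            D = actin.diffusivity_um2_s * 1.0 / max(L, 1e-6)
            x = np.empty(n_frames)
            y = np.empty(n_frames)
            x[0] = rng.uniform(0, W)
            y[0] = rng.uniform(0, H)
            theta = np.full(n_frames, rng.uniform(0, np.pi))
            if L > actin.confinement_length_um and D > 0:
                # harmonic trap: exact OU with stationary sd = trap radius
                sig = actin.confinement_radius_um
                relax = sig ** 2 / D
                cx, cy = x[0], y[0]
                for k in range(1, n_frames):
                    x[k] = _ou_step(x[k - 1], cx, relax, sig ** 2, dt_s, rng)
                    y[k] = _ou_step(y[k - 1], cy, relax, sig ** 2, dt_s, rng)
            else:
                step_sd = np.sqrt(2.0 * D * dt_s)
                x[1:] = x[0] + np.cumsum(rng.normal(0, step_sd, n_frames - 1))
                y[1:] = y[0] + np.cumsum(rng.normal(0, step_sd, n_frames - 1))
            particles.append(ParticleTruth(
                id=next_id, species="actin", birth_frame=0,
                death_frame=n_frames - 1, x_um=x, y_um=y, theta_rad=theta,
                state=np.full(n_frames, STATE_RANDOM, dtype=object),
                length_um=L, contrast=contrast,
                dwell_s=n_frames * dt_s, censored=True))
            next_id += 1

    if myosin is not None and myosin.arrival_rate_per_s > 0:
        T = n_frames * dt_s
        n_arrivals = rng.poisson(myosin.arrival_rate_per_s * T)
        arrival_times = np.sort(rng.uniform(0, T, n_arrivals))
        for t_arr in arrival_times:
            dwell = float(sample_dwell_times(myosin.dwell_mixture, 1, rng)[0])
            birth = int(t_arr / dt_s)
            death_unclipped = int((t_arr + dwell) / dt_s)
            censored = death_unclipped >= n_frames
            death = min(death_unclipped, n_frames - 1)
            if death < birth or birth >= n_frames:
                continue
            p = _simulate_bound_myosin(myosin, birth, death, dt_s, rng,
                                       fov_um, next_id, dwell, censored)
            particles.append(p)
            next_id += 1

    return GroundTruth(particles=particles, n_frames=n_frames, dt_s=dt_s,
                       fov_um=fov_um)


def _simulate_bound_myosin(cfg: MyosinSceneConfig, birth: int, death: int,
                           dt: float, rng, fov_um, pid: int,
                           dwell: float, censored: bool) -> ParticleTruth:
    n = death - birth + 1
    W, H = fov_um
    L = max(rng.normal(*cfg.length_nm), 100.0) / 1000.0
    contrast = min(rng.normal(*cfg.contrast), -1e-6)
    x = np.empty(n)
    y = np.empty(n)
    theta_unfolded = np.empty(n)  # tracked unfolded; folded to [0, pi) on output
    state = np.empty(n, dtype=object)
    x[0] = rng.uniform(0, W)
    y[0] = rng.uniform(0, H)
    theta_unfolded[0] = rng.uniform(0, np.pi)
    stat_var = cfg.orientation_variance_rad2

    run_lengths: list[float] = []
    step_sd_rand = np.sqrt(2.0 * cfg.D_random_um2_s * dt)

    k = 0
    while k < n:
        directed = rng.uniform() < cfg.p_directed
        if directed:
            dur = _draw_duration(cfg.directed_duration_s, cfg.run_min_s, rng)
        else:
            dur = _draw_duration(cfg.random_duration_s, dt, rng)
        seg_frames = max(1, int(round(dur / dt)))
        k_end = min(n, k + seg_frames)
        if directed:
            speed = max(rng.normal(*cfg.v_directed_um_s), 0.02)
            sign = rng.choice([-1.0, 1.0])
            bearing = theta_unfolded[k] + (0.0 if sign > 0 else np.pi)
            path = 0.0
            for j in range(k, k_end):
                state[j] = STATE_DIRECTED
                if j + 1 < n:
                    dx = speed * dt * np.cos(bearing)
                    dy = speed * dt * np.sin(bearing)
                    x[j + 1] = x[j] + dx
                    y[j + 1] = y[j] + dy
                    theta_unfolded[j + 1] = _ou_step(
                        theta_unfolded[j], bearing, cfg.orientation_relax_s,
                        stat_var, dt, rng)
                    if j + 1 < k_end:
                        path += np.hypot(dx, dy)
            run_lengths.append(path + speed * dt)  # include closing step
        else:
            anchor = theta_unfolded[k]
            for j in range(k, k_end):
                state[j] = STATE_RANDOM
                if j + 1 < n:
                    x[j + 1] = x[j] + rng.normal(0, step_sd_rand)
                    y[j + 1] = y[j] + rng.normal(0, step_sd_rand)
                    theta_unfolded[j + 1] = _ou_step(
                        theta_unfolded[j], anchor, cfg.orientation_relax_s,
                        stat_var, dt, rng)
        k = k_end

    return ParticleTruth(
        id=pid, species="myosin", birth_frame=birth, death_frame=death,
        x_um=x, y_um=y, theta_rad=np.mod(theta_unfolded, np.pi), state=state,
        length_um=L, contrast=contrast, dwell_s=dwell, censored=censored,
        run_lengths_um=run_lengths)


# --------------------------------------------------------------------------
# Rendering
# --------------------------------------------------------------------------

def _particle_field(p: ParticleTruth, k: int, shape, px_um: float,
                    sigma_px: float, myosin_width_nm: float = 100.0):
    """Render one particle into a local patch; returns (patch, (i0, j0)) or None.

    The particle's geometric support (line segment for actin, ellipse for
    myosin) is rasterized at sub-pixel resolution, blurred with the Gaussian
    PSF, and scaled so its extreme value equals the particle's (negative)
    target peak contrast.  Rendering is linear by construction: the frame is
    the pixelwise sum of independently scaled particle patches.
    """
    H, W = shape
    x = p.x_um[k] / px_um            # pixel units (pixel centre at +0.5)
    y = p.y_um[k] / px_um
    theta = p.theta_rad[k]
    L_px = p.length_um / px_um
    half = int(np.ceil(L_px / 2 + 4 * sigma_px + 3))
    i0 = int(np.floor(y)) - half
    j0 = int(np.floor(x)) - half
    i1 = i0 + 2 * half + 1
    j1 = j0 + 2 * half + 1
    if i1 <= 0 or j1 <= 0 or i0 >= H or j0 >= W:
        return None
    size = 2 * half + 1
    patch = np.zeros((size, size))
    # local sub-pixel coordinates of the centroid (pixel-centre convention)
    cy = y - i0 - 0.5
    cx = x - j0 - 0.5
    ux, uy = np.cos(theta), np.sin(theta)
    if p.species == "myosin":
        # the length parameter is the *half-maximum* length (the operational
        # length definition used for filament measurements); the half-max
        # points of an ellipse's chord profile sit at +-(sqrt(3)/2) a, so
        # the ellipse semi-axis is length / sqrt(3)
        a = max(L_px / np.sqrt(3.0), 0.5)
        b = max(myosin_width_nm / 2.0 / (px_um * 1000.0), 0.4)
        sub = 3  # supersampling for fractional pixel coverage
        offs = (np.arange(sub) + 0.5) / sub - 0.5
        ii, jj = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
        cov = np.zeros((size, size))
        for oy in offs:
            for ox in offs:
                dx = jj + ox - cx
                dy = ii + oy - cy
                t_par = dx * ux + dy * uy
                t_per = -dx * uy + dy * ux
                cov += ((t_par / a) ** 2 + (t_per / b) ** 2) <= 1.0
        patch = cov / sub ** 2
    else:  # actin: line segment, bilinear deposition every 0.2 px
        n_pts = max(int(np.ceil(L_px / 0.2)), 2)
        t = np.linspace(-L_px / 2, L_px / 2, n_pts)
        xs = cx + t * ux
        ys = cy + t * uy
        jf = np.floor(xs).astype(int)
        if_ = np.floor(ys).astype(int)
        fx = xs - jf
        fy = ys - if_
        for di, dj, wgt in ((0, 0, (1 - fy) * (1 - fx)), (0, 1, (1 - fy) * fx),
                            (1, 0, fy * (1 - fx)), (1, 1, fy * fx)):
            ii = if_ + di
            jj = jf + dj
            ok = (ii >= 0) & (ii < size) & (jj >= 0) & (jj < size)
            np.add.at(patch, (ii[ok], jj[ok]), wgt[ok])
    blurred = gaussian_filter(patch, sigma_px, mode="constant")
    peak = blurred.max()
    if peak <= 0:
        return None
    return blurred * (p.contrast / peak), (i0, j0)


def _add_patch(canvas: np.ndarray, patch: np.ndarray, origin) -> None:
    H, W = canvas.shape
    i0, j0 = origin
    h, w = patch.shape
    si0, sj0 = max(i0, 0), max(j0, 0)
    si1, sj1 = min(i0 + h, H), min(j0 + w, W)
    if si0 >= si1 or sj0 >= sj1:
        return
    canvas[si0:si1, sj0:sj1] += patch[si0 - i0:si1 - i0, sj0 - j0:sj1 - j0]


def static_fields(optics: OpticsConfig, seed: int = 0):
    """(roughness, fixed_pattern) static contrast fields for one movie.

    Glass roughness is a smooth (3-px correlated) Gaussian random field;
    fixed-pattern noise is per-pixel white.  Both are generated once per
    movie and are bit-identical under the same seed.
    """
    rng = np.random.default_rng(seed)
    shape = optics.fov_px
    rough = np.zeros(shape)
    if optics.roughness_amplitude > 0:
        rough = gaussian_filter(rng.normal(size=shape), 3.0)
        rough *= optics.roughness_amplitude / rough.std()
    pattern = np.zeros(shape)
    if optics.fixed_pattern_amplitude > 0:
        pattern = rng.normal(0.0, optics.fixed_pattern_amplitude, shape)
    return rough, pattern


def render_movie(truth: GroundTruth, optics: OpticsConfig,
                 seed: int = 0) -> ImageStack:
    """Render a ground-truth scene into a contrast movie.

    Each filament is rendered as its geometric support convolved with the
    Gaussian PSF and scaled to its (negative) target peak contrast; the
    static roughness and fixed-pattern fields are added once per movie and
    per-frame Gaussian shot noise on top.  Particles longer than the field
    of view trigger a warning and are clipped at the frame edge.
    """
    H, W = optics.fov_px
    px_um = optics.pixel_size_um
    sigma_px = optics.psf_sigma_px
    fov_w, fov_h = W * px_um, H * px_um
    too_long = [p.id for p in truth.particles
                if p.length_um > min(fov_w, fov_h)]
    if too_long:
        warnings.warn(f"{len(too_long)} particle(s) longer than the field of "
                      f"view; rendering clipped at the frame edge")
    rough, pattern = static_fields(optics, seed)
    noise_rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    frames = np.zeros((truth.n_frames, H, W), dtype=np.float64)
    for f in range(truth.n_frames):
        canvas = frames[f]
        for p in truth.alive_at(f):
            res = _particle_field(p, f - p.birth_frame, (H, W), px_um, sigma_px)
            if res is not None:
                _add_patch(canvas, res[0], res[1])
        canvas += rough
        canvas += pattern
        if optics.shot_noise_sd > 0:
            canvas += noise_rng.normal(0.0, optics.shot_noise_sd, (H, W))
    return ImageStack(frames=frames.astype(np.float32), dt_s=truth.dt_s,
                      pixel_size_nm=optics.pixel_size_nm,
                      meta={"source": "myofil.simulate.render_movie",
                            "seed": seed, "wavelength_nm": optics.wavelength_nm})


def compose_raw(stack: ImageStack, flatfield: np.ndarray) -> ImageStack:
    """Compose a raw (uncorrected) stack as ``flatfield * (1 + contrast)``.

    This is the multiplicative model that flat-field division inverts:
    dividing the result by ``flatfield`` and subtracting one recovers the
    contrast stack exactly.
    """
    raw = flatfield[None, :, :] * (1.0 + stack.frames)
    return stack.with_frames(raw, note="compose_raw")


def moving_stage_stack(optics: OpticsConfig, n_frames: int = 200,
                       n_particles: int = 15, seed: int = 0) -> tuple[ImageStack, np.ndarray]:
    """Emulate a moving-stage flat-field acquisition.

    Returns ``(raw_stack, pattern)`` where ``pattern`` is the static
    illumination/fixed-pattern field (mean 1) and each raw frame is
    ``pattern * (1 + scene_t + noise)`` with the particle scene decorrelated
    from frame to frame (the moving stage shows fresh sample positions each
    frame), so the per-pixel temporal median recovers ``pattern``.
    """
    rng = np.random.default_rng(seed)
    rough, fp = static_fields(optics, seed)
    pattern = 1.0 + rough + fp
    H, W = optics.fov_px
    px_um = optics.pixel_size_um
    frames = np.empty((n_frames, H, W), dtype=np.float64)
    c_mean, c_sd = SPECIES_CONTRAST[("myosin", optics.wavelength_nm)]
    for f in range(n_frames):
        scene = np.zeros((H, W))
        for _ in range(n_particles):
            p = ParticleTruth(
                id=0, species="myosin", birth_frame=0, death_frame=0,
                x_um=np.array([rng.uniform(0, W * px_um)]),
                y_um=np.array([rng.uniform(0, H * px_um)]),
                theta_rad=np.array([rng.uniform(0, np.pi)]),
                state=np.array([STATE_RANDOM], dtype=object),
                length_um=0.52, contrast=min(rng.normal(c_mean, c_sd), -1e-6),
                dwell_s=1.0, censored=False)
            res = _particle_field(p, 0, (H, W), px_um, optics.psf_sigma_px)
            if res is not None:
                _add_patch(scene, res[0], res[1])
        noise = rng.normal(0.0, optics.shot_noise_sd, (H, W))
        frames[f] = pattern * (1.0 + scene + noise)
    stk = ImageStack(frames=frames, dt_s=optics.dt_s,
                     pixel_size_nm=optics.pixel_size_nm,
                     meta={"source": "moving_stage_stack", "seed": seed})
    return stk, pattern
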