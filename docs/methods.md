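# Methods

This note documents the models behind `myofil`, the parameter choices that
matter, the numerical details, and what the synthetic benchmark does and
does not establish about real recordings.

## Imaging model

The detected iSCAT intensity is I ∝ r² + s² + 2 r |s| cos φ, with r the
glass–water reflectivity (~0.065), s the scattered field and φ their phase
difference. For the weak scatterers considered here the cross term
dominates, the contrast (background-divided signal minus one) is negative
and scales linearly with molecular mass. The renderer implements exactly
this scaling and nothing more: each particle's geometric support (a line
segment for an actin filament, an ellipse for a myosin filament) is
convolved with a Gaussian PSF of 210-nm FWHM and scaled so its extremal
pixel equals the particle's target peak contrast. No coherent speckle,
defocus PSF structure or |s|² saturation is modelled; the reduced contrast
ratio observed at 445 nm for very heavy particles is therefore outside the
simulator's scope (the calculators handle it as arithmetic only).

A modelling convention worth noting: the myosin `length_nm` parameter is
the *half-maximum* length — the operational definition used by the
length-measurement operation (distance between the half-maximal points of
the axial contrast profile). Because the half-max points of an ellipse's
chord profile sit at ±(√3/2)·a, the rendered ellipse semi-axis is
length/√3, making the simulator's length parameter and the measurement's
output the same quantity.

Two setups are preconfigured: 445 nm (23.4 nm/px, 50 fps) and 635 nm
(31.8 nm/px, 25 fps). Species contrast calibrations (mean ± sd): actin
−0.058 ± 0.015 (445 nm) and −0.002 ± 0.001 (635 nm); myosin −0.120 ± 0.026
and −0.017 ± 0.006. Default shot noise of 0.001 contrast units per pixel
and frame puts a single myosin filament at SNR ≈ 17 at 635 nm. Static
glass roughness is a 3-px-correlated Gaussian random field (amplitude
0.005, matching the contrast fluctuations of a decorated bilayer);
fixed-pattern noise is per-pixel white (amplitude 0.002). Both static
fields are generated once per movie and removed exactly by flat-field or
median processing.

## Scene dynamics

**Actin.** Filament lengths are normal (default 2.0 ± 1.5 µm, floored at
0.2 µm). Translational diffusivity scales as 1/length with D(1 µm) =
0.005 µm²/s, chosen so a short filament's 5-s MSD is ≈ 0.1 µm² — the
mobility scale of membrane-tethered filaments. Filaments longer than
1.5 µm are confined by the surrounding meshwork, modelled as a harmonic
trap (exact Ornstein–Uhlenbeck updates) with stationary r.m.s. excursion
0.15 µm per axis, giving an MSD plateau of 4·0.15² = 0.09 µm². Orientation
is held fixed per filament (quasi-static rods).

**Myosin.** Filaments land as a Poisson process and dwell for a time drawn
from an exponential mixture; the default mixture (0.55, 0.34 s),
(0.35, 2.26 s), (0.10, 10.9 s) uses the three characteristic binding
timescales of muscle myosin II filaments. Only the time constants of such
mixtures are commonly reported; the component *fractions* here are a
package choice fixed once (a fast-dominated spectrum, ~55/35/10), used
consistently by the generator, the benchmark scenarios and the acceptance
computations. Dwells are drawn first and clipped by the recording window,
with censoring flagged, so dwell-time estimators can be tested with and
without censoring.

While bound, a filament alternates segments: each new segment is directed
with probability `p_directed`, else random. Random segments are Brownian
(D = 0.005 µm²/s). Directed segments move at a per-run speed drawn from
N(0.46, 0.20²) µm/s along a fixed run bearing equal to the body axis at
run start (one of the two axial directions, chosen at random — orientation
is axial and polarity is unobservable). During a run the body axis
fluctuates about the bearing as an Ornstein–Uhlenbeck process with
stationary variance k_B T / K_tor (equipartition; K_tor default 7.5 pN nm,
in the 7.5–9.2 pN nm range typical of these filaments) and a 1-s
relaxation time — the OU process is the minimal stationary Gaussian model
consistent with a single stationary-variance constraint. The velocity
follows the fixed bearing rather than the fluctuating axis; this is what
makes the orientation–velocity angle α an observable realization of the
thermal fluctuation whose variance the stiffness estimator inverts.

## Preprocessing

Flat-fielding divides by the per-pixel temporal median of a moving-stage
acquisition; the simulator composes raw frames multiplicatively
(pattern × (1 + contrast)) so the round trip is exact. Preaveraging uses
non-overlapping blocks and multiplies the frame interval (25 Hz / 5 →
effective 5 Hz, dt = 0.2 s — the default analysis timebase). Temporal
median subtraction operates on non-overlapping windows (whole-sequence or,
typically, 50 effective frames = 10 s); a rolling variant exists behind a
flag but is O(window) more work and was not needed. The
`last_frame_minus_median` mode (10-s segments) isolates freshly landed
filaments for length measurements.

## Detection and linking

Background level and r.m.s. come from iterative 3σ clipping. Pixels below
level − k·rms (default k = 4) are segmented by 8-connectivity; components
of ≥ 9 px become detections. No printed thresholds exist for this step;
the defaults are set so the Gaussian-tail false-positive expectation on a
noise-only 256² frame is below one detection, which the test suite asserts.
Centroids and the orientation/axes come from contrast-weighted first and
second moments; semi-axes are reported as twice the r.m.s. extent (exact
for a uniformly weighted ellipse). Multi-threshold deblending is
deliberately absent: touching particles merge and are rejected downstream
by the linker's area gate — the analysis targets isolated filaments, and
the benchmark scene reflects that regime.

Linking gates (displacement ≤ 0.5 µm/frame-pair, axial Δθ ≤ 45°, area
ratio ≤ 2, gap ≤ 1 frame) are configuration with recorded defaults, since
only the gate *criteria* are specified by the method; 0.5 µm/frame covers
a 0.46 µm/s directed step at 0.2 s plus diffusion. Assignment is greedy by
ascending displacement (adequate for sparse fields — the benchmark purity
bound guards this); a Hungarian mode exists behind a flag. A track's dwell
time spans first to last frame plus one frame interval, counting bridged
gaps as bound; tracks touching the first or last recorded frame are
censored and dropped by default.

## Motion analysis

MSDs are time-averaged over all overlapping pairs. The
parallel/perpendicular decomposition projects each lag displacement onto
the axis/normal of the orientation at the pair's earlier time (a midpoint
variant exists behind a flag); the two components sum to the total
identically. The reference diffusivity D_ref is the slope/4 of a line fit
to the first five lags of the ensemble MSD of randomly moving tracks.

Directed/random segmentation slides a 10-frame (2-s) window along the
track; a window is a directed candidate when its net displacement exceeds
k·√(4 D_ref Δt_window). Since the squared net displacement of 2-D
diffusion is exponential with mean 4 D Δt, the per-window false-candidate
probability is e^(−k²); the default k = 2.5 (≈ 0.2%) keeps the
false-directed frame fraction of a pure-diffusion track below 5%, the
calibration oracle asserted in the tests. Frames are labelled by majority
vote of the candidate windows covering them, and directed runs shorter
than 10 frames are reassigned to random. (Requiring instead a run of ≥ 10
consecutive candidate *windows* cannot mark a 10-frame directed run — a
10-frame run supports at most 9 overlapping windows — so frame-level
voting is used; it recovers ≥ 85% of frames on 2-s/4-s alternating
simulations.) In the directed-rich contractile state, D_ref estimated
in-run is inflated by the directed motion itself; the pipeline therefore
accepts an explicit D_ref measured from a remodeling recording, which is
how the threshold is meant to be derived, and otherwise performs one
refinement pass using only tracks classified fully random.

α angles compare each step's velocity bearing with the axial orientation
at the step start, folded to [−90°, 90°]; the FWHM is interpolated from a
5°-bin histogram (a Gaussian-fit FWHM would presume a shape the histogram
need not have) and the variance is the mean squared α. K_tor = k_B T /
⟨Δα²⟩ with k_B·295.15 K = 4.075 pN nm (room temperature, 22 °C). Step-wise
bearings add discretization noise on top of the thermal fluctuation, so
K_tor inferred from short-step tracks is biased slightly low; the
estimator is exact on the angle process itself (10% recovery at 10⁴ steps
is asserted).

## Kinetic fitting

Dwell-time mixtures are fitted on unbinned data by maximizing the
likelihood of f(t) = Σ aᵢ τᵢ⁻¹ e^(−t/τᵢ) renormalized on [t_min, t_max];
histogram bins are display-only. The default t_min is 0.3 s for
tracking-derived dwells (the detection limit) and 1.0 s for
kymograph-derived ones; t_max defaults to +∞ (censored events are dropped
rather than right-truncated, matching the extraction default; a finite
t_max is supported). The maximization is EM in the truncated-component
parametrization: with one-sided truncation the M-step for each τ is a
responsibility-weighted mean of (t − t_min) in closed form; with two-sided
truncation it is a scalar root-find. Multistart (quantile-spread starting
points plus seeded jitter, best of five) guards against local optima, and
EM's monotonicity makes the fit deterministic given data and seed.
Reported fractions are those of the untruncated mixture. Components whose
time constants collapse within 1% trigger a refit with k−1 (flagged).
Model order is selected by BIC — deterministic and requiring no
nested-test calibration — with likelihood-ratio p-values reported
alongside for comparison. Confidence intervals are nonparametric bootstrap
percentiles (≥ 200 replicates, refit from the point estimate).

Run lengths use the left-truncated exponential MLE (sample mean minus the
truncation point). Velocity distributions use a closed-form Gaussian
(k = 1) or a two-component EM with deterministic median-split
initialization (k = 2), falling back to k = 1 when a component
degenerates. Correlation of run length vs dwell time is reported as
Pearson r with two-sided p separately below and above a 3-s split;
distribution shifts are tested with the two-sample KS statistic above a
minimum dwell.

## Benchmark scenarios and problem sizes

The two shipped scenarios differ in dwell mixture, directed probability
and speed: "remodeling" ((0.55, 0.34), (0.35, 2.26), (0.10, 10.9) s;
p_directed = 0.2; v = 0.20 ± 0.13 µm/s) and "contractile" ((0.50, 0.41),
(0.35, 2.46), (0.15, 11.0) s; p_directed = 0.6; v = 0.46 ± 0.20 µm/s).
Default pipeline geometry is 128² px at 635 nm, 1500 native frames
(preaveraged ×5 → 300 effective frames, 60 s) — sized so that a full run
takes seconds while still yielding ~50 binding events. At this problem
size the pipeline resolves the overall dwell scale and the
directed-fraction contrast between scenarios (≥ 2.5×), not all three
mixture components; the component-level recovery checks instead run the
fitting machinery directly on simulated dwells at the reported sample
sizes (6400, 14,016 and 1133), where the time constants are recovered
within their reported confidence spans. The detection/tracking benchmark
uses ten always-bound filaments started on a jittered grid — the
isolated-filament regime the method targets; fields dense enough for
frequent crossings would need the deblending that is deliberately out of
scope.

## What passing tests do and do not show

The generator reproduces the *statistical structure* the analysis assumes:
mass-proportional negative contrast, Gaussian PSF, static backgrounds,
shot noise, exponential-mixture dwells, two-state motion, OU orientation
fluctuations. It omits network mechanics (crosslink forces, contractile
flows, cluster formation beyond an ROI contrast drift), coherent optical
artefacts, detector nonlinearity and stage drift. Passing the suite
therefore shows the pipeline is correct and well-calibrated under its own
model assumptions — not that those assumptions exhaust real recordings.

## Known limitations

- No deblending: touching particles merge; dense fields lose recall.
- Greedy linking can switch identities when particles pass within the
  displacement gate of each other.
- The censored-dwell treatment drops incomplete events rather than using a
  right-censored likelihood (available as an option but not the default),
  matching the extraction convention at the cost of efficiency.
- K_tor from step-wise α angles is biased low by bearing discretization at
  short steps; use directed runs with substantial per-step displacement.
- BIC model selection under-resolves close time constants at small n, by
  design of the parsimony penalty.
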