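# myofil

Label-free single-particle analysis of myosin II filament dynamics in
membrane-bound actin networks imaged by interferometric scattering (iSCAT)
microscopy — with a ground-truthed synthetic movie generator so every stage
of the analysis is testable without experimental data.

## The problem

In reconstituted acto-myosin networks on supported lipid bilayers, muscle
myosin II filaments bind actin transiently, alternate between diffusive
("weak-binding") and processive (directed) motion, and collectively switch
the network from a remodeling to a contractile state as ATP is depleted.
iSCAT microscopy images these dynamics without labels: the interferometric
contrast

I ∝ r² + s² + 2 r |s| cos φ

is dominated by the interference term for weak scatterers, so contrast
scales linearly with molecular mass and is negative (dark) for particles at
the coverslip. Actin filaments (−0.058 ± 0.015 at 445 nm; −0.002 ± 0.001 at
635 nm) and the much heavier myosin II filaments (−0.120 ± 0.026;
−0.017 ± 0.006) are distinguishable by contrast alone.

`myofil` is for researchers doing quantitative single-particle analysis of
such recordings. It implements:

- **simulate** — synthetic iSCAT stacks: diffusing/confined actin rods,
  Poisson-arriving myosin filaments with exponential-mixture dwell times,
  alternating Brownian and directed motion, Ornstein–Uhlenbeck orientation
  noise with stationary variance k_B T / K_tor, Gaussian PSF, static
  roughness/fixed-pattern fields and shot noise, plus a full truth table.
- **preproc** — flat-field division (temporal median of moving-stage
  frames), frame preaveraging (25 Hz / 5 → effective 5 Hz), and temporal
  median subtraction that removes quasi-static structure while mobile
  particles survive.
- **detect** — Source-Extractor-style segmentation of dark elongated
  particles; position, extent and axial orientation from contrast-weighted
  image moments.
- **link** — gated greedy nearest-neighbour tracking (displacement,
  axial Δθ, area-ratio gates, gap closing) and dwell-time extraction with
  explicit censoring of tracks touching the recording boundary.
- **motion** — time-averaged MSD with exact parallel/perpendicular
  decomposition (components sum to the total), log-log slopes,
  directed/random segmentation against a diffusive envelope
  k·√(4 D_ref Δt), orientation–velocity angle (α) statistics, and
  torsional stiffness via k_B T = ⟨Δα²⟩ K_tor.
- **kinetics** — maximum-likelihood fitting of dwell-time mixtures
  f(t) = Σ aᵢ τᵢ⁻¹ e^(−t/τᵢ) renormalized on the observation window
  [t_min, t_max] (unbinned data, EM with multistart), bootstrap CIs, BIC
  model selection, run-length and Gaussian-mixture velocity fits, Pearson
  split-regime correlations, two-sample KS tests, and kymographs.
- **masscalc** — contrast statistics and the mass/density arithmetic that
  follows from the linear mass–contrast scaling.
- **pipeline** — seed-reproducible end-to-end runs of two benchmark
  scenarios ("remodeling", "contractile") and scoring of every stage
  against the simulator's ground truth.

## Worked example

Fitting a truncated triple-exponential dwell-time mixture
(`examples/03_dwell_time_fitting.py`):

```text
fitted 3-component truncated mixture on n=9002 dwells:
  component 0: fraction 0.57, tau = 0.34 s  [95% CI 0.31-0.37]
  component 1: fraction 0.33, tau = 2.26 s  [95% CI 2.05-2.45]
  component 2: fraction 0.10, tau = 10.59 s  [95% CI 9.70-11.49]
BIC model selection over k = 1..3 chooses k = 3
```

14,016 dwell times were drawn from the mixture (0.55, 0.34 s),
(0.35, 2.26 s), (0.10, 10.9 s); events below the 0.3-s detection limit are
unobservable, yet the truncation-aware likelihood recovers the fast time
constant without bias. The three timescales correspond to single-head
binding (~0.3 s), one-sided multi-head binding (~2 s) and two-sided binding
of the bipolar filament (~11 s).

The calculators print the mass/density arithmetic directly
(`examples/05_mass_and_density_calculators.py`):

```text
myosin/actin mass per diffraction-limited spot: 21840 / 2520 kDa -> ratio 8.7
measured contrast ratio at 635 nm: 8.5 (mass scaling holds)
2% NTA lipid at 70 A^2/lipid -> 28,571 lipids/um^2 -> 3,600-5,700 His-tagged linkers/um^2
deepest network contrast -0.348 / single filament -0.058 -> 6 filaments -> 48 nm layer height
```

Each example in `examples/` is a short narrative script for one capability;
the `myofil` command exposes the same stages for shell use
(`myofil simulate | preproc | detect | track | fit-dwell | run`).

## Documentation

`docs/methods.md` describes the models, parameter choices, numerical
details and known limitations.
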