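"""Contrast, mass and geometry calculators.

In iSCAT the detected intensity is I = |E_i|^2 {r^2 + s^2 + 2 r |s| cos(phi)};
for weak scatterers the interference term dominates and the interferometric
contrast scales linearly with molecular mass, so contrast ratios between
species report their mass ratios per diffraction-limited spot.  This module
collects the pure arithmetic built on that scaling: species contrast
statistics, mass- and contrast-ratio predictions, lipid/protein surface
densities, filament lengths from half-maximum profile crossings, and actin
layer thickness from contrast stoichiometry.

Every calculator returns the raw value; rounding helpers mirror common
reporting conventions (1 decimal for ratios, 2 significant figures for
densities) without discarding the unrounded number.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preproc import temporal_median_subtract
from .stack import ImageStack

__all__ = [
    "ContrastModel", "SpeciesContrast", "round_sig",
    "contrast_stats", "mass_per_spot", "mass_ratio", "contrast_ratio",
    "nta_lipid_density", "tag_protein_density", "linear_tether_density",
    "layer_thickness", "cylinder_surface_density", "filament_length_halfmax",
    "roi_contrast_delta", "A2_to_um2", "um2_to_A2", "nm2_to_um2",
]

#: 1 Angstrom^2 in um^2
A2_IN_UM2 = 1e-8
#: 1 nm^2 in um^2
NM2_IN_UM2 = 1e-6


def A2_to_um2(a2: float) -> float:
    return a2 * A2_IN_UM2


def um2_to_A2(um2: float) -> float:
    return um2 / A2_IN_UM2


def nm2_to_um2(nm2: float) -> float:
    return nm2 * NM2_IN_UM2


def round_sig(x: float, sig: int) -> float:
    """Round to ``sig`` significant figures."""
    if x == 0:
        return 0.0
    from math import floor, log10
    return round(x, -int(floor(log10(abs(x)))) + (sig - 1))


@dataclass
class ContrastModel:
    """Linear mass-to-contrast scaling of the interferometric signal.

    ``contrast_per_kDa`` is negative for dark particles; ``phase_phi`` is
    fixed at pi (destructive interference) for this system.
    """

    reflectivity_r: float = 0.065
    contrast_per_kDa: float = -1e-5
    phase_phi: float = np.pi

    def __post_init__(self) -> None:
        if self.contrast_per_kDa >= 0:
            raise ValueError("contrast_per_kDa must be negative for dark particles")

    def contrast(self, mass_kDa: float) -> float:
        return self.contrast_per_kDa * mass_kDa


@dataclass
class SpeciesContrast:
    """Normal-fit summary of contrast measurements along one species."""

    species: str
    wavelength_nm: int
    mean: float
    sd: float
    n_measurements: int


def contrast_stats(profile_values, species: str = "unknown",
                   wavelength_nm: int = 635) -> SpeciesContrast:
    """Gaussian fit (mean and standard deviation) of contrast measurements."""
    v = np.asarray(profile_values, dtype=float)
    if v.size < 10:
        raise ValueError("need at least 10 contrast measurements")
    return SpeciesContrast(species=species, wavelength_nm=wavelength_nm,
                           mean=float(v.mean()), sd=float(v.std(ddof=1)),
                           n_measurements=int(v.size))


def mass_per_spot(n_units: float, unit_mass_kDa: float) -> float:
    """Total mass within a diffraction-limited spot: n_units * unit mass (kDa)."""
    if n_units <= 0 or unit_mass_kDa <= 0:
        raise ValueError("inputs must be positive")
    return n_units * unit_mass_kDa


def mass_ratio(mass_a_kDa: float, mass_b_kDa: float) -> float:
    """Mass ratio a/b; report with ``round(x, 1)`` for 1-decimal convention."""
    if mass_b_kDa == 0:
        raise ValueError("zero denominator")
    return mass_a_kDa / mass_b_kDa


def contrast_ratio(c_num: float, c_den: float) -> float:
    """Magnitude ratio |c_num| / |c_den| of two contrast values."""
    if c_den == 0:
        raise ValueError("zero denominator")
    return abs(c_num) / abs(c_den)


def nta_lipid_density(mole_fraction: float, area_per_lipid_A2: float) -> float:
    """Surface density (um^-2) of a lipid species at a given mole fraction.

    density = fraction / area per lipid, e.g. 2% NTA lipid at 70 A^2 per
    lipid gives 28,571 um^-2.
    """
    if not 0 < mole_fraction <= 1:
        raise ValueError("mole_fraction must be in (0, 1]")
    if area_per_lipid_A2 <= 0:
        raise ValueError("area per lipid must be positive")
    return mole_fraction / (area_per_lipid_A2 * A2_IN_UM2)


def tag_protein_density(lipid_density_per_um2: float,
                        lipids_per_tag_range: tuple[float, float],
                        sig: int = 2) -> tuple[float, float]:
    """Surface density range (um^-2) of His-tagged protein on NTA lipids.

    Each decahistidine tag occupies ``lipids_per_tag_range`` = (lo, hi) NTA
    lipids, so the protein density spans density/hi .. density/lo, rounded
    to ``sig`` significant figures.
    """
    lo, hi = lipids_per_tag_range
    if not (1 <= lo <= hi):
        raise ValueError("lipids per tag must satisfy 1 <= lo <= hi")
    return (round_sig(lipid_density_per_um2 / hi, sig),
            round_sig(lipid_density_per_um2 / lo, sig))


def linear_tether_density(filament_width_um: float,
                          surface_density_per_um2: float) -> float:
    """Tethers per um of filament: footprint width x surface density."""
    if filament_width_um < 0 or surface_density_per_um2 < 0:
        raise ValueError("inputs must be non-negative")
    return filament_width_um * surface_density_per_um2


def layer_thickness(max_contrast_profile, single_filament_contrast: float,
                    filament_diameter_nm: float = 8.0) -> tuple[int, float]:
    """Actin layer thickness from contrast stoichiometry.

    The most negative contrast in the profile divided by the single-filament
    contrast gives the number of stacked filaments (rounded); height =
    n x filament diameter (8-nm actin filaments by default).  A profile
    that is nowhere negative gives n = 0.
    """
    if single_filament_contrast >= 0:
        raise ValueError("single filament contrast must be negative")
    prof = np.asarray(max_contrast_profile, dtype=float)
    depth = -prof.min()
    if depth <= 0:
        return 0, 0.0
    n = int(round(depth / abs(single_filament_contrast)))
    return n, n * filament_diameter_nm


def cylinder_surface_density(n_heads: float, radius_nm: float,
                             length_nm: float) -> float:
    """Motor-head surface density (um^-2) on a cylindrical filament.

    n / (2 pi r L); e.g. 100 heads on a 50-nm-radius, 700-nm-long cylinder
    give ~455 um^-2 (order 500).
    """
    if n_heads <= 0 or radius_nm <= 0 or length_nm <= 0:
        raise ValueError("inputs must be positive")
    area_um2 = 2.0 * np.pi * radius_nm * length_nm * NM2_IN_UM2
    return n_heads / area_um2


def filament_length_halfmax(profile, pixel_size_nm: float) -> float:
    """Filament length from the half-maximal crossings of an axial profile.

    The profile is the (negative) contrast along the filament's long axis,
    sampled at pixel centres.  The length is the distance between the two
    points where the depth crosses half its maximum, found by linear
    interpolation.  Multiple disjoint super-half-maximum regions mean the
    filament is not isolated and raise an error.
    """
    prof = np.asarray(profile, dtype=float)
    if prof.size < 3:
        raise ValueError("profile too short")
    depth = np.maximum(-prof, 0.0)
    peak = depth.max()
    if peak <= 0:
        raise ValueError("profile has no negative contrast")
    half = peak / 2.0
    above = depth >= half
    # require one contiguous super-half-max region
    changes = np.flatnonzero(np.diff(above.astype(int)))
    n_regions = np.count_nonzero(np.diff(above.astype(int)) == 1) + int(above[0])
    if n_regions != 1:
        raise ValueError(f"{n_regions} super-half-maximum regions; "
                         "filament not isolated")
    idx = np.flatnonzero(above)
    i0, i1 = idx[0], idx[-1]
    # left crossing between i0-1 and i0 (or half a pixel outside at the edge)
    if i0 == 0:
        left = -0.5
    else:
        frac = (half - depth[i0 - 1]) / (depth[i0] - depth[i0 - 1])
        left = i0 - 1 + frac
    if i1 == prof.size - 1:
        right = prof.size - 1 + 0.5
    else:
        frac = (depth[i1] - half) / (depth[i1] - depth[i1 + 1])
        right = i1 + frac
    return float((right - left) * pixel_size_nm)


def roi_contrast_delta(stack: ImageStack, roi_inside: np.ndarray,
                       roi_outside: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Median-subtracted mean contrast over time inside and outside an ROI.

    Subtracts the per-pixel temporal median and returns the per-frame mean
    of the residual within each mask — the time course of material moving
    into (negative-going) or out of a region such as a myosin cluster.
    """
    inside = np.asarray(roi_inside, dtype=bool)
    outside = np.asarray(roi_outside, dtype=bool)
    if inside.shape != stack.frame_shape or outside.shape != stack.frame_shape:
        raise ValueError("masks must match the frame shape")
    if not inside.any() or not outside.any():
        raise ValueError("masks must be nonempty")
    if np.any(inside & outside):
        raise ValueError("masks overlap")
    filt = temporal_median_subtract(stack).filtered.frames
    series_in = filt[:, inside].mean(axis=1)
    series_out = filt[:, outside].mean(axis=1)
    return series_in, series_out
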