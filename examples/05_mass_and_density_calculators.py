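"""Contrast-to-mass arithmetic and surface-density calculators.

All quantities follow from the linear scaling of interferometric contrast
with molecular mass and simple geometry.
"""

from myofil import masscalc as mc

m_myo = mc.mass_per_spot(42, 520)     # 42 myosin dimers x 520 kDa
m_act = mc.mass_per_spot(60, 42)      # 60 actin subunits x 42 kDa per spot
print(f"myosin/actin mass per diffraction-limited spot: "
      f"{m_myo:.0f} / {m_act:.0f} kDa -> ratio {mc.mass_ratio(m_myo, m_act):.1f}")
print(f"measured contrast ratio at 635 nm: "
      f"{mc.contrast_ratio(0.017, 0.002):.1f} (mass scaling holds)")
print(f"at 445 nm: {mc.contrast_ratio(0.12, 0.06):.1f} "
      f"(direct-scattering term reduces large-particle contrast)")

rho_lipid = mc.nta_lipid_density(0.02, 70.0)
lo, hi = mc.tag_protein_density(rho_lipid, (5, 8))
print(f"2% NTA lipid at 70 A^2/lipid -> {rho_lipid:,.0f} lipids/um^2 "
      f"-> {lo:,.0f}-{hi:,.0f} His-tagged linkers/um^2")
print(f"linkers under a 5-nm-wide actin filament: "
      f"{mc.linear_tether_density(0.005, hi):.1f} per um")

n, height = mc.layer_thickness([-0.348], -0.058, 8.0)
print(f"deepest network contrast -0.348 / single filament -0.058 "
      f"-> {n} filaments -> {height:.0f} nm layer height")

rho_heads = mc.cylinder_surface_density(100, 50, 700)
print(f"100 myosin heads on a 50 x 700 nm cylinder: "
      f"{rho_heads:.0f} heads/um^2 (~{mc.round_sig(rho_heads, 1):.0f})")
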