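"""Steric H...H deshielding and torsion-scan Boltzmann analysis.

Compares the inside-proton H...H contact of planar (Z)- vs (E)-hexatriene,
fits the r**-6 deshielding constant from synthetic distance/shift pairs, and
shows that a secondary torsional minimum 2.37 kcal/mol above the planar
conformer leaves the Boltzmann-averaged shifts essentially unchanged.
"""

import numpy as np

from trienenmr import (
    WeightingSpec,
    analyze_torsion_scan,
    fit_steric_power_law,
    hh_distances,
    steric_shift,
)
from trienenmr.synthetic import TrieneSpec, build_triene_geometry, make_torsion_scan

for pattern, name in ((("E", "Z", "E"), "(Z)-hexatriene"),
                      (("E", "E", "E"), "(E)-hexatriene")):
    geometry = build_triene_geometry(TrieneSpec(pattern=pattern))
    pairs = hh_distances(geometry.atoms, "auto", bonds=geometry.bonds)
    shortest = min(pairs, key=lambda item: item[1])
    print(f"{name}: shortest non-bonded H...H = {shortest[1]:.2f} A "
          f"(atoms {shortest[0]}), steric term at a_s=25: "
          f"{steric_shift(shortest[1], 25.0):.2f} ppm")

radii = np.linspace(1.8, 2.6, 9)
fit = fit_steric_power_law([(r, 50.0 / r**6) for r in radii])
print(f"\npower-law fit on noiseless 50/r^6 data: a_s = {fit.a_s:.4f}, "
      f"n = {fit.exponent_n:.4f}, r2(log-log) = {fit.r2_fit:.6f}")

summary = analyze_torsion_scan(make_torsion_scan(gap_kcal=2.37), WeightingSpec())
print(f"\ntorsion scan minima (angle, dG): {summary.minima}")
print(f"weight of the planar (180 deg) well: "
      f"{summary.minima_weights[180.0]*100:.1f} %")
for site in summary.averaged_shifts:
    avg = summary.averaged_shifts[site]
    gmin = summary.global_minimum_shifts[site]
    print(f"{site}: grid-averaged {avg:.3f} ppm vs global-minimum {gmin:.3f} ppm "
          f"(|diff| = {abs(avg - gmin):.3f})")
print("A sub-0.02 ppm difference means the secondary well can be neglected "
      "when predicting shifts.")
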