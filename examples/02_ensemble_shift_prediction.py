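"""Conformer-ensemble 1H shift prediction on a synthetic triene.

Generates a two-conformer ensemble of an (E,Z,E)-octatriene-like molecule
with the surrogate shielding model (0.02 ppm noise), Boltzmann-averages the
shieldings, references them to the synthetic TMS value, and regresses the
predicted site shifts against the surrogate's own noiseless values.
"""

from trienenmr import ensemble_site_shifts, fit_linear
from trienenmr.synthetic import (
    SurrogateParams,
    TrieneSpec,
    build_triene_geometry,
    generate_ensemble,
)

spec = TrieneSpec(pattern=("E", "Z", "E"), chain_lengths=(1, 1))
wells = [(180.0, 0.0), (120.0, 0.8)]  # planar global minimum + skew well

noisy = generate_ensemble(spec, wells, SurrogateParams(noise_sd=0.02, seed=42))
clean = generate_ensemble(spec, wells, SurrogateParams(noise_sd=0.0))
sites = build_triene_geometry(spec).sites
sigma_ref = SurrogateParams().sigma_ref

calc = ensemble_site_shifts(noisy, sites, sigma_ref)
truth = ensemble_site_shifts(clean, sites, sigma_ref)

print("site   predicted delta (ppm)   noiseless delta (ppm)")
for label in sorted(calc.shifts):
    print(f"{label:>4}   {calc.shifts[label]:21.3f}   {truth.shifts[label]:21.3f}")
print("\nconformer weights:",
      {k: round(v, 4) for k, v in calc.weights_used.items()})

report = fit_linear(calc.shifts, truth.shifts)
print(f"regression vs noiseless truth: r2 = {report.r2:.4f}, "
      f"mse = {report.mse:.5f} ppm^2, slope = {report.slope:.3f}, "
      f"intercept = {report.intercept:.3f}")
print("An r2 near 1 with slope near 1 says the ensemble machinery adds no "
      "systematic error beyond the injected noise; the inside protons (H3/H6 "
      "of the Z unit) sit far downfield of the rest.")
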