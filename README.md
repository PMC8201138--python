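# trienenmr

Conformer-ensemble ¹H NMR chemical-shift analysis for conjugated trienes —
the molecules behind conjugated linolenic acids (α-/β-eleostearic and
punicic acid), hexadecatrienyl moth pheromones, and model compounds such as
1,3,5-hexatriene and 2,4,6-octatriene.

These systems pack three conjugated C=C bonds whose olefinic resonances
crowd into a ~1 ppm window, so literature assignments are frequently
ambiguous or wrong. Computed shieldings resolve this: predicted shifts that
correlate linearly with experiment validate an assignment, and deviations
from linearity localize the mislabelled resonances. `trienenmr` implements
the downstream analysis of that workflow:

* **Boltzmann thermochemistry** — conformer populations
  `p_i = g_i e^{-ΔG_i/RT} / Σ_j g_j e^{-ΔG_j/RT}` at configurable
  temperature (default 298.15 K, R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹), and
  population-weighted ensemble shieldings `σ̄ = Σ_i p_i σ_i`.
* **TMS referencing and site averaging** — `δ = σ_ref − σ`, with arithmetic
  averaging over rotation/symmetry-equivalent protons (methyl rotors,
  symmetric pairs).
* **Regression quality control** — OLS of δ_calc (y) on δ_exp (x) reporting
  R², mean square error (SSR/n), intercept and slope; the slope/intercept
  deviation from (1, 0) measures the systematic error, which
  `scaled_shifts` removes via `δ_scaled = (δ_calc − intercept)/slope`.
* **Assignment revision** — exhaustive permutation search of experimental
  labels inside exchange groups (explicit, or auto-clustered resonances
  closer than 0.10 ppm), optimizing R² with deterministic tie-breaking.
* **Steric deshielding** — non-bonded H···H distances, the
  `δ_steric = a_s/r⁶` power law (free or fixed exponent, log–log fit), a
  cos θ/rⁿ geometry-weighted variant, and torsion-scan analysis (minima,
  gaps, Boltzmann-averaged shifts).
* **Synthetic surrogate** — an idealized internal-coordinate triene builder
  plus an additive shielding model (base value per proton type + 0.45 ppm
  geminal-alkyl increment + r⁻⁶ steric term + seeded Gaussian noise) that
  stands in for the quantum-chemistry stage in tests and demos.

Literature experimental shift tables and conformer free energies for the
seven C18:3 / C16:3 isomers ship as packaged CSV fixtures.

## Worked example

```python
from trienenmr import WeightingSpec, boltzmann_populations
from trienenmr.io import conformer_records

records, printed = conformer_records("9E11E13E", "B3LYP")
populations = boltzmann_populations(records, WeightingSpec(temperature=298.15))
for r in records:
    print(r.conformer_id, f"{100 * populations[r.conformer_id]:.2f} %")
```

prints

```
A 33.41 %
B 61.35 %
C 0.39 %
D 2.53 %
E 2.32 %
```

— the equilibrium populations of the five low-energy conformers of the
all-E C18:3 acid (skew/skew′ allylic wells dominate; the eclipsed syn
conformers are nearly empty), matching the literature percentages to
better than 0.01 percentage points. The `examples/` directory holds one
narrative script per capability: conformer populations, ensemble shift
prediction, assignment revision, and steric/torsion analysis; each prints
the numbers it computes and a line on what they mean.

A thin CLI wraps the same functions
(`trienenmr populations|shifts|regress|revise|steric|scan|simulate|run`).

## Layout

```
src/trienenmr/     models, io, ensemble, regression, assignment, steric,
                   synthetic, pipeline, cli   (+ data/ fixtures)
tests/             pytest suite (unit, property and acceptance tests)
examples/          narrative scripts, one per capability
docs/methods.md    model assumptions, parameter choices, limitations
```
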