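# Methods

This note documents the models implemented in `trienenmr`, the defaults and
why they were chosen, what the synthetic surrogate does and does not
emulate, and the numerical conventions a user should know before trusting
the outputs.

## Scope

The package covers the *analysis* half of a computed-vs-experimental ¹H
shift workflow for conjugated trienes: thermochemistry → ensemble
averaging → referencing → regression QC → assignment revision, plus
geometry-based steric analysis. The electronic-structure half (geometry
optimization, frequency calculations, GIAO shielding tensors, continuum
solvation) is deliberately out of scope: shieldings and free energies enter
as file inputs (conformer-table CSV, minimal shielding-log dialect), or
from the synthetic surrogate. Solvent is carried as metadata only.

## Boltzmann thermochemistry

Populations are `p_i = g_i exp(−ΔG_i/RT) / Σ_j g_j exp(−ΔG_j/RT)`,
computed in log space (`logsumexp`) and renormalized exactly. Defaults:

* **T = 298.15 K, R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹.** The source conformer
  tables print ΔG and percentages but no temperature; 298.15 K reproduces
  every self-consistent printed row to ≤ 0.01 percentage points, so it is
  adopted as the default.
* **ΔG is the canonical weighting energy**; ΔE weighting is available via
  `WeightingSpec(energy_kind="electronic")` because both are commonly
  reported.
* **Degeneracy defaults to 1** — literature tables list conformers
  individually.

Two documented anomalies in the packaged free-energy fixture are *flagged*,
never silently absorbed: the punicic-acid D/E row at B3LYP (printed ΔG of
+3.83/+3.63 kcal/mol imply 0.06/0.09 %, not the printed 1.51/1.85 %), and
the 10Z-acetate rows whose printed populations sum to only 82–88 %
(unlisted conformers). `check_population_consistency` reports a row as
self-consistent only when every conformer agrees within 0.02 pp *and* the
reference column sums to 100 ± 0.05 %.

Energy units are kcal/mol throughout. Conformer-table energy columns with a
negative minimum are interpreted as absolute hartrees and converted with
627.5095 kcal/mol per hartree before re-zeroing; non-negative columns are
taken as already-relative and left verbatim (this makes re-zeroing
idempotent and write→read an identity).

## Ensemble shifts and referencing

Ensemble shieldings are the population-weighted mean per atom; shifts are
`δ = σ_ref − σ`. σ_ref (the TMS reference shielding) is a required
configuration input per method/basis/solvent — it is never guessed.
Equivalent-proton averaging (methyl rotors, symmetric pairs) is an
arithmetic mean applied *after* ensemble averaging; because referencing and
averaging are affine, the order of weighting and referencing commutes, and
the fast-rotation limit is the only physical assumption. Atom indices are
1-based everywhere, following quantum-chemistry file conventions.

## Regression quality control

Ordinary least squares with δ_exp as abscissa and δ_calc as ordinate; the
opposite orientation is available behind a flag for sensitivity checks.
The mean square error is defined as SSR/n (population convention) and the
choice is recorded in the report's `conventions` block so serialized
reports are self-describing. Reports with fewer than 3 paired sites are
refused. `compare_reports` returns one of four verdicts — improved,
worsened, indistinguishable, or *mixed* when R² and mse move in opposite
directions.

## Assignment revision

Literature revisions of overlapped triene assignments are done by
inspecting deviations from linearity; this package makes the criterion
explicit and exhaustive. Within each exchange group — explicit label sets,
or single-linkage clusters of experimental resonances with gaps below a
0.10 ppm window (overlapped triene resonances typically differ by
≤ 0.06 ppm) — every permutation of experimental labels is enumerated and
refit. The objective is max R² (equivalently min SSR at fixed label set),
with ties broken by smaller mse, then fewest transpositions, then
lexicographic order: the search is deterministic and seed-free. The
permutation count is capped (default 10⁶) with an explicit error rather
than silent truncation. Swaps permute *experimental* labels; δ_calc is
never altered. Coupling constants and NOE data are outside the objective.

Recovery behaviour under the default synthetic conditions (8 sites spread
over 5.4–6.8 ppm, one 4-site exchange group, 0.05 ppm experimental noise):
97 % of 200 seeded trials recover the planted truth, and 100 % at zero
noise. Denser groupings than ~0.2 ppm site spacing at comparable noise will
recover less often — the limit is information-theoretic, not algorithmic.

## Steric deshielding and torsion scans

Through-space H···H repulsion deshields sp² protons; the model is
`δ_steric = a_s/rⁿ` with n = 6 by default, fit by log–log least squares
(exponent free or fixed). A Cheney-style `cos θ/rⁿ` factor is provided as
an alternative regressor; it vanishes at θ = 90° and changes sign beyond.
Automatic pair selection takes non-bonded H pairs at least 4 covalent bonds
apart (geminal/vicinal pairs are dominated by through-bond effects) within
a 3.0 Å cutoff; bonds are inferred from covalent radii when no bond list is
given. No numeric a_s is shipped for real trienes — only the fitting
machinery; δ_excess baselines are user-supplied.

Torsion scans are analysed on their discrete grid (typically 10° spacing)
without interpolation: local minima by neighbour comparison (boundary
points count when below their single neighbour), gaps between minima, a
minima-level Boltzmann weighting, and a full-grid Boltzmann average of the
site shifts so that well *widths* as well as depths enter. For a two-well
profile with the literature-scale 2.37 kcal/mol gap, the planar well
carries 98.2 % of the weight and grid-averaged shifts sit within 0.02 ppm
of the global-minimum values — secondary minima are negligible for shift
prediction.

## The synthetic surrogate

`build_triene_geometry` constructs idealized geometries from internal
coordinates (C=C 1.34 Å, conjugated C–C 1.46 Å, saturated C–C 1.53 Å, C–H
1.09 Å; 120° at sp², 111° at sp³; E/Z double-bond torsions 180°/0°;
conjugated single bonds s-trans; saturated chains anti), with named
rotatable-bond overrides (skew +120°, skew′ −120°, syn 0°). Atom placement
uses standard three-atom internal-coordinate extension; torsion readback
agrees with the request to 10⁻⁹ degrees.

`surrogate_shieldings` emulates the physics the analysis assumes:
`σ_H = σ_ref − δ_type − Σ a_s/r⁶ + N(0, noise_sd)`, where δ_type is a base
shift per proton class (interior olefinic 5.90; terminal =CH₂ 5.15, plus a
0.45 ppm increment when the geminal partner is alkyl; allylic 2.00;
methylene 1.35; methyl 0.95 ppm) and the steric sum runs over the automatic
pair rule. The defaults were calibrated once against literature hexatriene
and octatriene shift tables and frozen; with a_s = 25 ppm Å⁶ the idealized
(Z)-hexatriene inside contact (1.71 Å) yields ≈ 1 ppm of excess
deshielding, placing the inside protons near 6.9 ppm.

What the surrogate reproduces: the qualitative ordering that drives the
analysis — inside protons of Z-configured units strongly deshielded
(approaching aromatic values), terminal =CH₂ protons the most shielded
olefinics, alkyl-substitution deshielding of ~0.45 ppm. What it does not:
ppm-exact DFT shieldings, ring-current/anisotropy effects, solvent shifts,
vibrational corrections, or conformer-dependent electronic structure.
Passing tests therefore certify the *analysis machinery* (weighting,
referencing, regression, search), not the accuracy of any quantum-chemistry
method on real spectra.

All stochastic generators take a mandatory seed and spawn one child stream
per conformer, so outputs are bit-reproducible.

## Numerical conventions and limitations

* Population vectors renormalize exactly; sums hold to 1e-12 (fractions).
* Regression matches the closed-form normal-equations solution to 1e-10.
* Torsion angles use the IUPAC sign convention on (−180, 180].
* JSON reports round floats to 1e-6 ppm and carry a config hash, package
  version and seed, so identical inputs give bit-identical files.
* The assignment search is exhaustive, hence exponential in group size;
  the cap exists to fail loudly instead of hanging.
* The steric fit requires strictly positive excess shifts (log domain);
  shielding-type H···H interactions (as in alkanes) are out of scope.
* Test-suite problem sizes (ensembles of ≤ 5 conformers, 8-site revision
  cases, 200-trial recovery studies, 19-point scans) were chosen as the
  smallest instances that exercise every code path and statistical claim.
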