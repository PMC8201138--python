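"""Boltzmann populations of literature triene conformers.

Loads the packaged relative free energies (kcal/mol) of the five low-energy
conformers of the all-E C18:3 conjugated fatty acid, converts them to
equilibrium populations at 298.15 K, and checks them against the
literature-printed percentages.
"""

from trienenmr import WeightingSpec, boltzmann_populations
from trienenmr.io import conformer_records
from trienenmr.pipeline import check_population_consistency

records, printed = conformer_records("9E11E13E", "B3LYP")
populations = boltzmann_populations(records, WeightingSpec(temperature=298.15))

print("conformer   dG (kcal/mol)   population (%)   literature (%)")
for record in records:
    pct = 100.0 * populations[record.conformer_id]
    print(f"{record.conformer_id:>9}   {record.dG_rel:13.2f}   {pct:14.2f}"
          f"   {printed[record.conformer_id]:14.2f}")

check = check_population_consistency(
    {cid: 100.0 * p for cid, p in populations.items()}, printed
)
print(f"\nself-consistent with the printed column: {check['self_consistent']} "
      f"(max deviation {check['max_abs_deviation_pp']:.3f} pp)")
print("A deviation above 0.02 pp would flag a transcription or thermochemistry "
      "problem in the input table.")
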