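"""Regression-driven revision of a scrambled resonance assignment.

Builds a synthetic case in which four overlapped experimental resonances
have been mislabelled (a seeded non-identity permutation), then searches all
within-group permutations for the assignment maximizing the calc-vs-exp
regression quality.
"""

from trienenmr import AssignmentMap, compare_reports, fit_linear
from trienenmr.assignment import SwapSearchSpec, optimize_assignment, revision_report
from trienenmr.synthetic import make_revision_case

calc, exp, truth = make_revision_case(n_sites=8, noise_sd=0.05, seed=7)
print("planted scramble:",
      {k: v for k, v in truth.mapping.items() if k != v})

spec = SwapSearchSpec(exchange_groups=tuple(truth.exchange_groups))
best_map, best_report, ranked = optimize_assignment(calc, exp, spec)

identity_report = fit_linear(calc, exp)
comparison = compare_reports(identity_report, best_report)
text, summary = revision_report(
    AssignmentMap.identity(sorted(calc.shifts)), best_map, comparison, exp
)

print(f"\nsearched {len(ranked)} candidate assignments")
print(f"identity assignment: r2 = {identity_report.r2:.4f}, "
      f"mse = {identity_report.mse:.5f}")
print(f"revised assignment:  r2 = {best_report.r2:.4f}, "
      f"mse = {best_report.mse:.5f}")
print(f"recovered the planted truth: {best_map.mapping == truth.mapping}\n")
print(text)
print("\nEach line names a proton whose experimental resonance was relabelled; "
      "the verdict confirms the revision improves both quality metrics.")
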