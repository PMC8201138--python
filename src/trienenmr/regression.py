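"""Linear-regression quality control of calculated vs experimental shifts.

The regression quality (R^2, mean square error, intercept, slope) of
delta_calc against delta_exp is the criterion for whether a shift-prediction
method reproduces experiment free of random error; the deviation of the slope
from unity and the intercept from zero measures the systematic error, which
``scaled_shifts`` removes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Union

import numpy as np
from scipy import stats

from .models import (
    AssignmentMap,
    ComparisonError,
    DegenerateFitError,
    EnsembleShiftSet,
    ExperimentalShiftSet,
    InsufficientDataError,
    MappingError,
    RegressionReport,
)

ShiftsLike = Union[EnsembleShiftSet, ExperimentalShiftSet, Mapping[str, float]]


def _as_shift_map(obj: ShiftsLike) -> Mapping[str, float]:
    return obj.shifts if hasattr(obj, "shifts") else obj


def fit_linear(
    calc: ShiftsLike,
    exp: ShiftsLike,
    assignment: AssignmentMap | None = None,
    orientation: str = "calc_on_exp",
) -> RegressionReport:
    """OLS fit of delta_calc (ordinate) vs delta_exp (abscissa).

    ``assignment`` maps computed-site labels to experimental resonance labels
    (identity where omitted).  ``orientation="exp_on_calc"`` swaps the axes
    for sensitivity checks.  mse is SSR/n.
    """
    calc_map = _as_shift_map(calc)
    exp_map = _as_shift_map(exp)
    mapping = assignment.mapping if assignment is not None else {}
    pairs = []
    for site, delta_calc in calc_map.items():
        exp_label = mapping.get(site, site)
        if exp_label not in exp_map:
            raise MappingError(
                f"assignment sends {site!r} to {exp_label!r}, absent from the "
                "experimental table"
            )
        pairs.append((site, delta_calc, exp_map[exp_label]))
    if len(pairs) < 3:
        raise InsufficientDataError(f"need >= 3 paired sites, got {len(pairs)}")

    labels = [p[0] for p in pairs]
    y = np.array([p[1] for p in pairs])
    x = np.array([p[2] for p in pairs])
    if orientation == "exp_on_calc":
        x, y = y, x
    elif orientation != "calc_on_exp":
        raise ValueError(f"unknown orientation {orientation!r}")
    if np.ptp(x) == 0:
        raise DegenerateFitError("all abscissa values identical; OLS undefined")

    fit = stats.linregress(x, y)
    fitted = fit.intercept + fit.slope * x
    residuals = y - fitted
    ssr = float(np.sum(residuals**2))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if sst == 0 else max(0.0, 1.0 - ssr / sst)
    return RegressionReport(
        r2=r2,
        mse=ssr / len(pairs),
        intercept=float(fit.intercept),
        slope=float(fit.slope),
        residuals={lab: float(r) for lab, r in zip(labels, residuals)},
        n_points=len(pairs),
        conventions={"orientation": orientation, "mse_def": "ssr_over_n"},
    )


def scaled_shifts(report: RegressionReport, calc: ShiftsLike) -> dict[str, float]:
    """Systematic-error-corrected shifts: (delta_calc - intercept) / slope."""
    if abs(report.slope) < 1e-6:
        raise DegenerateFitError(f"slope {report.slope!r} too close to zero")
    calc_map = _as_shift_map(calc)
    return {
        site: float((delta - report.intercept) / report.slope)
        for site, delta in calc_map.items()
    }


@dataclass(frozen=True)
class ComparisonRecord:
    """Change in regression quality between two reports (b relative to a)."""

    delta_r2: float
    delta_mse: float
    verdict: str  # improved | worsened | indistinguishable | mixed

    def to_dict(self) -> dict:
        return {"delta_r2": self.delta_r2, "delta_mse": self.delta_mse,
                "verdict": self.verdict}


def compare_reports(
    a: RegressionReport,
    b: RegressionReport,
    r2_tol: float = 1e-9,
    mse_tol: float = 1e-9,
) -> ComparisonRecord:
    """Verdict on whether report b improves on report a.

    Both reports must cover the same computed-site set.  Metrics that move in
    opposite directions yield the verdict "mixed".
    """
    if set(a.residuals) != set(b.residuals):
        raise ComparisonError("reports cover different site sets")
    d_r2 = b.r2 - a.r2
    d_mse = b.mse - a.mse
    sign_r2 = 0 if abs(d_r2) <= r2_tol else (1 if d_r2 > 0 else -1)
    sign_mse = 0 if abs(d_mse) <= mse_tol else (-1 if d_mse > 0 else 1)
    if sign_r2 == sign_mse == 0:
        verdict = "indistinguishable"
    elif sign_r2 >= 0 and sign_mse >= 0:
        verdict = "improved"
    elif sign_r2 <= 0 and sign_mse <= 0:
        verdict = "worsened"
    else:
        verdict = "mixed"
    return ComparisonRecord(delta_r2=float(d_r2), delta_mse=float(d_mse), verdict=verdict)
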