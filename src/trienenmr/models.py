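"""Domain types for conformer-ensemble NMR shift analysis of conjugated trienes.

Conventions used throughout the package:

* energies are relative free (or electronic) energies in kcal/mol, re-zeroed to
  the ensemble minimum;
* isotropic shieldings sigma and chemical shifts delta are in ppm, with
  ``delta = sigma_ref - sigma`` (TMS reference);
* torsion angles are in degrees on (-180, 180] (IUPAC sign convention);
* atom indices are 1-based, following the quantum-chemistry file convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

Atom = tuple[str, float, float, float]  # (element, x, y, z) in angstrom


class TrieneNMRError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(TrieneNMRError):
    """Input table violates the documented column schema."""


class ShieldingLogError(TrieneNMRError):
    """Shielding log contains no parsable isotropic-shielding lines."""


class FixtureLookupError(TrieneNMRError, KeyError):
    """Unknown packaged-fixture name."""


class MissingEnergyError(TrieneNMRError):
    """A conformer lacks the energy kind requested for Boltzmann weighting."""


class InconsistentEnsembleError(TrieneNMRError):
    """Conformers of one ensemble disagree on their shielded-atom index set."""


class CoverageError(TrieneNMRError):
    """A proton site references an atom with no computed shift."""


class InsufficientDataError(TrieneNMRError):
    """Fewer data points than the operation can meaningfully use."""


class MappingError(TrieneNMRError):
    """Assignment map does not cover the experimental labels needed."""


class DegenerateFitError(TrieneNMRError):
    """Regression slope too close to zero (or data collinearity degenerate)."""


class ComparisonError(TrieneNMRError):
    """Two regression reports cover different site sets."""


class SearchSpaceError(TrieneNMRError):
    """Permutation search space exceeds the configured cap."""


class ScanFormatError(TrieneNMRError):
    """Torsion scan has duplicate angles or too few points."""


class GeometrySpecError(TrieneNMRError):
    """Invalid triene build specification."""


@dataclass
class ConformerRecord:
    """One conformer: relative energies, torsions, geometry and shieldings.

    ``dG_rel``/``dE_rel`` are in kcal/mol relative to the ensemble minimum.
    ``shieldings`` maps 1-based atom index -> isotropic shielding in ppm.
    """

    conformer_id: str
    dG_rel: float
    dE_rel: Optional[float] = None
    degeneracy: int = 1
    torsions: dict[str, float] = field(default_factory=dict)
    geometry: Optional[list[Atom]] = None
    shieldings: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.degeneracy < 1:
            raise ValueError(
                f"conformer {self.conformer_id!r}: degeneracy must be >= 1"
            )
        if self.geometry is not None:
            n = len(self.geometry)
            bad = [i for i in self.shieldings if not 1 <= i <= n]
            if bad:
                raise ValueError(
                    f"conformer {self.conformer_id!r}: shielding atom indices "
                    f"{sorted(bad)} outside geometry of {n} atoms"
                )


def validate_ensemble(conformers: list[ConformerRecord]) -> None:
    """Check the ensemble-level invariant: dG_rel >= 0 with a zero minimum."""
    if not conformers:
        raise InsufficientDataError("empty conformer ensemble")
    dgs = [c.dG_rel for c in conformers]
    if min(dgs) < -1e-9 or not any(abs(g) < 1e-9 for g in dgs):
        raise ValueError(
            "relative free energies must be >= 0 with at least one conformer "
            f"at 0.0 kcal/mol (got minimum {min(dgs):g})"
        )


@dataclass(frozen=True)
class ProtonSite:
    """A labelled set of rotation/symmetry-equivalent proton atom indices."""

    label: str
    atom_indices: frozenset[int]
    molecule_id: str = ""

    def __post_init__(self) -> None:
        if not self.atom_indices:
            raise ValueError(f"site {self.label!r}: atom_indices must be nonempty")


@dataclass
class ExperimentalShiftSet:
    """Experimental 1H shifts (ppm) keyed by site label, with provenance."""

    molecule_id: str
    solvent: str = "CHCl3"
    shifts: dict[str, float] = field(default_factory=dict)
    source: str = ""

    def __post_init__(self) -> None:
        bad = [k for k, v in self.shifts.items() if not math.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite experimental shifts for sites {bad}")


@dataclass
class EnsembleShiftSet:
    """Boltzmann-averaged calculated shifts per site, with provenance."""

    molecule_id: str
    shifts: dict[str, float]
    weights_used: dict[str, float] = field(default_factory=dict)
    sigma_ref: float = float("nan")
    temperature: float = 298.15

    def __post_init__(self) -> None:
        if self.weights_used:
            total = sum(self.weights_used.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"conformer weights sum to {total!r}, not 1")
        bad = [k for k, v in self.shifts.items() if not math.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite calculated shifts for sites {bad}")


def count_transpositions(mapping: dict[str, str]) -> int:
    """Minimal number of transpositions realizing the permutation.

    The mapping must be a bijection on its own key set (site labels to
    experimental labels drawn from the same label universe); the count is
    sum over cycles of (cycle length - 1).
    """
    seen: set[str] = set()
    n_swaps = 0
    for start in mapping:
        if start in seen or start not in mapping:
            continue
        length = 0
        node = start
        while node not in seen:
            seen.add(node)
            length += 1
            node = mapping[node]
            if node not in mapping:  # maps outside the key set: fixed point-ish
                break
        n_swaps += max(length - 1, 0)
    return n_swaps


@dataclass
class AssignmentMap:
    """Bijection computed-site label -> experimental resonance label."""

    mapping: dict[str, str]
    exchange_groups: list[frozenset[str]] = field(default_factory=list)
    n_swaps: int = 0

    def __post_init__(self) -> None:
        values = list(self.mapping.values())
        if len(set(values)) != len(values):
            raise ValueError("assignment mapping is not a bijection")
        for src, dst in self.mapping.items():
            if src == dst:
                continue
            if not any(src in g and dst in g for g in self.exchange_groups):
                raise ValueError(
                    f"permuted pair ({src!r} -> {dst!r}) lies outside every "
                    "exchange group"
                )

    @classmethod
    def identity(cls, labels: list[str]) -> "AssignmentMap":
        return cls(mapping={lab: lab for lab in labels})

    @classmethod
    def from_permutation(
        cls, mapping: dict[str, str], exchange_groups: list[frozenset[str]]
    ) -> "AssignmentMap":
        return cls(
            mapping=dict(mapping),
            exchange_groups=list(exchange_groups),
            n_swaps=count_transpositions(mapping),
        )


@dataclass
class RegressionReport:
    """OLS quality report for delta_calc vs delta_exp.

    ``mse`` is the mean squared residual SSR/n (population convention, recorded
    in ``conventions``); ``residuals`` are delta_calc - fitted, in ppm, keyed
    by computed-site label.
    """

    r2: float
    mse: float
    intercept: float
    slope: float
    residuals: dict[str, float]
    n_points: int
    conventions: dict[str, str] = field(
        default_factory=lambda: {"orientation": "calc_on_exp", "mse_def": "ssr_over_n"}
    )

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise InsufficientDataError(
                f"regression needs >= 3 points, got {self.n_points}"
            )
        if self.mse < 0 or self.r2 > 1 + 1e-12:
            raise ValueError("invalid regression statistics (mse < 0 or r2 > 1)")

    def to_dict(self) -> dict:
        return {
            "n_points": self.n_points,
            "r2": self.r2,
            "mse": self.mse,
            "intercept": self.intercept,
            "slope": self.slope,
            "residuals": dict(self.residuals),
            "conventions": dict(self.conventions),
        }


@dataclass
class TorsionScanPoint:
    """One grid point of a torsion scan: angle, energies and site shifts."""

    angle: float
    dE_rel: float
    dG_rel: Optional[float] = None
    site_shifts: dict[str, float] = field(default_factory=dict)


@dataclass
class StericModelFit:
    """Fitted steric-deshielding power law delta = a_s / r**n."""

    a_s: float
    exponent_n: float
    r2_fit: float
    pairs_used: list[tuple[str, str, float]] = field(default_factory=list)
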