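"""Boltzmann thermochemistry and conformer-ensemble shift computation.

Populations follow p_i = g_i exp(-dG_i/RT) / sum_j g_j exp(-dG_j/RT) with
R = 1.9872e-3 kcal/(mol K) and T defaulting to 298.15 K; ensemble shieldings
are the population-weighted mean per atom, chemical shifts are referenced to
TMS as delta = sigma_ref - sigma, and symmetry/rotation-equivalent protons
(methyl rotors, symmetric pairs) are averaged arithmetically in the
fast-exchange limit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy.special import logsumexp

from .models import (
    ConformerRecord,
    CoverageError,
    EnsembleShiftSet,
    InconsistentEnsembleError,
    InsufficientDataError,
    MissingEnergyError,
    ProtonSite,
)

logger = logging.getLogger(__name__)

GAS_CONSTANT_KCAL = 1.9872e-3  # kcal / (mol K)


@dataclass(frozen=True)
class WeightingSpec:
    """Temperature and energy choice for Boltzmann weighting."""

    temperature: float = 298.15
    energy_kind: str = "free_energy"  # or "electronic"
    gas_constant: float = GAS_CONSTANT_KCAL

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (kelvin)")
        if self.energy_kind not in ("free_energy", "electronic"):
            raise ValueError(f"unknown energy_kind {self.energy_kind!r}")


def _energy(record: ConformerRecord, spec: WeightingSpec) -> float:
    if spec.energy_kind == "free_energy":
        return record.dG_rel
    if record.dE_rel is None:
        raise MissingEnergyError(
            f"conformer {record.conformer_id!r} has no electronic energy"
        )
    return record.dE_rel


def boltzmann_populations(
    conformers: list[ConformerRecord], spec: WeightingSpec = WeightingSpec()
) -> dict[str, float]:
    """Equilibrium population fraction per conformer id (sums to 1)."""
    if not conformers:
        raise InsufficientDataError("no conformers to weight")
    energies = np.array([_energy(c, spec) for c in conformers], dtype=float)
    log_g = np.log([c.degeneracy for c in conformers])
    log_w = log_g - energies / (spec.gas_constant * spec.temperature)
    log_p = log_w - logsumexp(log_w)
    populations = np.exp(log_p)
    populations /= populations.sum()  # exact renormalization
    return {c.conformer_id: float(p) for c, p in zip(conformers, populations)}


def ensemble_shieldings(
    conformers: list[ConformerRecord], populations: Mapping[str, float]
) -> dict[int, float]:
    """Population-weighted mean isotropic shielding per atom index."""
    if not conformers:
        raise InsufficientDataError("no conformers to average")
    reference = set(conformers[0].shieldings)
    for c in conformers[1:]:
        if set(c.shieldings) != reference:
            diff = sorted(set(c.shieldings) ^ reference)
            raise InconsistentEnsembleError(
                f"conformer {c.conformer_id!r} disagrees on atom indices {diff}"
            )
    out = {}
    for atom in sorted(reference):
        out[atom] = float(
            sum(populations[c.conformer_id] * c.shieldings[atom] for c in conformers)
        )
    return out


def shieldings_to_shifts(sigma: Mapping, sigma_ref: float) -> dict:
    """TMS-referenced chemical shifts: delta = sigma_ref - sigma, per key."""
    if not math.isfinite(sigma_ref):
        raise ValueError("sigma_ref must be finite")
    return {key: float(sigma_ref - value) for key, value in sigma.items()}


def average_equivalent(
    atom_shifts: Mapping[int, float],
    sites: Iterable[ProtonSite],
    *,
    molecule_id: str = "",
    weights_used: Mapping[str, float] | None = None,
    sigma_ref: float = float("nan"),
    temperature: float = 298.15,
) -> EnsembleShiftSet:
    """Arithmetic mean over each site's equivalent protons (fast-rotation limit)."""
    sites = list(sites)
    site_shifts: dict[str, float] = {}
    used: set[int] = set()
    for site in sites:
        missing = sorted(i for i in site.atom_indices if i not in atom_shifts)
        if missing:
            raise CoverageError(
                f"site {site.label!r} references atoms {missing} with no shift"
            )
        values = [atom_shifts[i] for i in sorted(site.atom_indices)]
        site_shifts[site.label] = float(np.mean(values))
        used |= set(site.atom_indices)
    unreferenced = sorted(set(atom_shifts) - used)
    if unreferenced:
        logger.warning("atoms %s carry shifts but belong to no site", unreferenced)
    return EnsembleShiftSet(
        molecule_id=molecule_id or (sites[0].molecule_id if sites else ""),
        shifts=site_shifts,
        weights_used=dict(weights_used or {}),
        sigma_ref=sigma_ref,
        temperature=temperature,
    )


def ensemble_site_shifts(
    conformers: list[ConformerRecord],
    sites: Iterable[ProtonSite],
    sigma_ref: float,
    spec: WeightingSpec = WeightingSpec(),
    molecule_id: str = "",
) -> EnsembleShiftSet:
    """Full chain: populations -> ensemble shieldings -> shifts -> site means."""
    populations = boltzmann_populations(conformers, spec)
    sigma = ensemble_shieldings(conformers, populations)
    atom_shifts = shieldings_to_shifts(sigma, sigma_ref)
    return average_equivalent(
        atom_shifts,
        sites,
        molecule_id=molecule_id,
        weights_used=populations,
        sigma_ref=sigma_ref,
        temperature=spec.temperature,
    )
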