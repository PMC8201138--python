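"""Through-space H...H steric deshielding and torsion-scan analysis.

Non-bonded H...H repulsion perturbs the electron cloud of a proton, reducing
its diamagnetic shielding; for sp2 protons the effect is a deshielding that
follows a power law delta_steric = a_s / r**n with n ~ 6, where r is the
internuclear H...H distance.  A geometry-weighted variant scales the term by
cos(theta), theta being the angle between the H...H line and the H-C bond.
Torsion scans are analysed on their discrete grid: local minima, energy gaps,
and Boltzmann-weighted shift averages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np

from .ensemble import WeightingSpec
from .models import Atom, ScanFormatError, StericModelFit, TorsionScanPoint, TrieneNMRError

COVALENT_RADII = {"H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66}


class DomainError(TrieneNMRError, ValueError):
    """Argument outside the model's domain (e.g. r <= 0)."""


def infer_bonds(geometry: Sequence[Atom], scale: float = 1.25) -> list[tuple[int, int]]:
    """Distance-based covalent bond inference (1-based atom index pairs)."""
    coords = np.array([[x, y, z] for _, x, y, z in geometry])
    bonds = []
    for i, j in combinations(range(len(geometry)), 2):
        ri = COVALENT_RADII.get(geometry[i][0], 0.77)
        rj = COVALENT_RADII.get(geometry[j][0], 0.77)
        if np.linalg.norm(coords[i] - coords[j]) <= scale * (ri + rj):
            bonds.append((i + 1, j + 1))
    return bonds


def hh_distances(
    geometry: Sequence[Atom],
    pairs: Iterable[tuple[int, int]] | str = "auto",
    bonds: Optional[Sequence[tuple[int, int]]] = None,
    min_bond_separation: int = 4,
    cutoff: float = 3.0,
) -> list[tuple[tuple[int, int], float]]:
    """Euclidean H...H distances for requested or auto-selected pairs.

    Auto mode returns non-bonded hydrogen pairs separated by at least
    ``min_bond_separation`` covalent bonds with r <= cutoff; geminal and
    vicinal pairs are excluded because through-bond effects dominate there.
    Duplicate/reversed explicit pairs are deduplicated.
    """
    coords = np.array([[x, y, z] for _, x, y, z in geometry])
    n = len(geometry)

    def dist(i: int, j: int) -> float:
        return float(np.linalg.norm(coords[i - 1] - coords[j - 1]))

    if pairs != "auto":
        out = []
        seen = set()
        for i, j in pairs:
            if not (1 <= i <= n and 1 <= j <= n):
                raise IndexError(f"atom pair ({i}, {j}) outside geometry of {n} atoms")
            key = (min(i, j), max(i, j))
            if key in seen:
                continue
            seen.add(key)
            out.append((key, dist(*key)))
        return out

    if bonds is None:
        bonds = infer_bonds(geometry)
    graph = nx.Graph()
    graph.add_nodes_from(range(1, n + 1))
    graph.add_edges_from(bonds)
    hydrogens = [i + 1 for i, atom in enumerate(geometry) if atom[0] == "H"]
    if len(hydrogens) < 2:
        raise DomainError("need at least two hydrogens for steric analysis")
    lengths = dict(nx.all_pairs_shortest_path_length(graph))
    out = []
    for i, j in combinations(hydrogens, 2):
        separation = lengths.get(i, {}).get(j)
        if separation is not None and separation < min_bond_separation:
            continue
        r = dist(i, j)
        if r <= cutoff:
            out.append(((i, j), r))
    return out


def steric_shift(r: float, a_s: float, n: float = 6.0) -> float:
    """Steric deshielding contribution a_s / r**n (ppm)."""
    if r <= 0:
        raise DomainError(f"H...H distance must be positive, got {r!r}")
    return a_s / r**n


def fit_steric_power_law(
    points: Sequence[tuple[float, float]], fix_n: Optional[float] = None
) -> StericModelFit:
    """Log-log least-squares fit of delta_excess = a_s / r**n.

    With ``fix_n`` the exponent is held fixed and only a_s is fitted.
    r2_fit is the coefficient of determination on the log-log scale.
    """
    if len(points) < 3:
        raise DomainError(f"need >= 3 (r, delta) points, got {len(points)}")
    r = np.array([p[0] for p in points], dtype=float)
    d = np.array([p[1] for p in points], dtype=float)
    if np.any(r <= 0):
        raise DomainError("all distances must be positive")
    if np.any(d <= 0):
        raise DomainError("delta_excess must be positive (log-log fit)")
    log_r, log_d = np.log(r), np.log(d)
    if fix_n is None:
        slope, intercept = np.polyfit(log_r, log_d, 1)
        exponent = -float(slope)
    else:
        exponent = float(fix_n)
        intercept = float(np.mean(log_d + exponent * log_r))
    fitted = intercept - exponent * log_r
    ss_res = float(np.sum((log_d - fitted) ** 2))
    ss_tot = float(np.sum((log_d - log_d.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return StericModelFit(
        a_s=float(np.exp(intercept)),
        exponent_n=exponent,
        r2_fit=r2,
        pairs_used=[("", "", float(x)) for x in r],
    )


def cheney_geometry_factor(r: float, theta: float, n: float = 6.0) -> float:
    """Angle-weighted steric regressor cos(theta)/r**n.

    theta (degrees) is the angle between the H...H internuclear line and the
    H-C bond of the proton of interest; the factor vanishes at 90 degrees and
    changes sign beyond it.
    """
    if r <= 0:
        raise DomainError(f"H...H distance must be positive, got {r!r}")
    cos_t = math.cos(math.radians(theta))
    if abs(theta - 90.0) < 1e-12:
        cos_t = 0.0
    return cos_t / r**n


@dataclass
class ScanSummary:
    """Minima, gaps and Boltzmann-weighted shift statistics of a torsion scan."""

    minima: list[tuple[float, float]]          # (angle, energy) of local minima
    gaps: dict[float, float]                   # minimum angle -> gap above global min
    minima_weights: dict[float, float]         # Boltzmann weights over minima only
    grid_weights: dict[float, float]           # Boltzmann weights over the full grid
    averaged_shifts: dict[str, float]          # grid-Boltzmann-averaged site shifts
    global_minimum_shifts: dict[str, float]    # shifts at the global-minimum angle
    shift_extrema: dict[str, dict] = field(default_factory=dict)
    energy_kind_used: str = "free_energy"


def analyze_torsion_scan(
    scan: Sequence[TorsionScanPoint], spec: WeightingSpec = WeightingSpec()
) -> ScanSummary:
    """Locate scan minima and Boltzmann-average the site shifts.

    Minima are grid points below both neighbours (boundary points count when
    below their single neighbour); no interpolation is performed.  Weighting
    uses dG where present on every point, otherwise dE.  Shift averages are
    taken over the whole grid so that well widths, not only depths, enter.
    """
    if len(scan) < 5:
        raise ScanFormatError(f"need >= 5 scan points, got {len(scan)}")
    angles = [p.angle for p in scan]
    if len(set(angles)) != len(angles):
        raise ScanFormatError("duplicate angles in torsion scan")
    points = sorted(scan, key=lambda p: p.angle)

    use_dg = all(p.dG_rel is not None for p in points)
    energy = np.array([p.dG_rel if use_dg else p.dE_rel for p in points], dtype=float)
    energy = energy - energy.min()

    minima: list[tuple[float, float]] = []
    for k, p in enumerate(points):
        left = energy[k - 1] if k > 0 else np.inf
        right = energy[k + 1] if k < len(points) - 1 else np.inf
        if energy[k] < left and energy[k] < right:
            minima.append((p.angle, float(energy[k])))
    if not minima:  # flat profile: every point ties; report the first
        minima = [(points[0].angle, float(energy[0]))]

    gap0 = min(e for _, e in minima)
    gaps = {angle: float(e - gap0) for angle, e in minima}

    rt = spec.gas_constant * spec.temperature
    w_min = np.exp(-np.array([e for _, e in minima]) / rt)
    w_min /= w_min.sum()
    minima_weights = {angle: float(w) for (angle, _), w in zip(minima, w_min)}

    w_grid = np.exp(-energy / rt)
    w_grid /= w_grid.sum()
    grid_weights = {p.angle: float(w) for p, w in zip(points, w_grid)}

    sites = sorted({s for p in points for s in p.site_shifts})
    averaged, extrema = {}, {}
    for site in sites:
        values = np.array([p.site_shifts.get(site, np.nan) for p in points])
        mask = ~np.isnan(values)
        if not mask.any():
            continue
        w = w_grid[mask] / w_grid[mask].sum()
        averaged[site] = float(np.sum(w * values[mask]))
        sub_angles = np.array([p.angle for p in points])[mask]
        sub_values = values[mask]
        extrema[site] = {
            "max_shift": float(sub_values.max()),
            "max_angle": float(sub_angles[sub_values.argmax()]),
            "min_shift": float(sub_values.min()),
            "min_angle": float(sub_angles[sub_values.argmin()]),
        }

    global_angle = min(gaps, key=lambda a: (gaps[a], a))
    global_point = next(p for p in points if p.angle == global_angle)
    return ScanSummary(
        minima=minima,
        gaps=gaps,
        minima_weights=minima_weights,
        grid_weights=grid_weights,
        averaged_shifts=averaged,
        global_minimum_shifts=dict(global_point.site_shifts),
        shift_extrema=extrema,
        energy_kind_used="free_energy" if use_dg else "electronic",
    )
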