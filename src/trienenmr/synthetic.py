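"""Surrogate for the quantum-chemistry stage.

Builds idealized 3-D geometries of conjugated trienes from internal
coordinates, generates per-proton isotropic shieldings with the assumed
physics of the shift analysis (base value per proton type + geminal alkyl
increment + r**-6 through-space H...H steric deshielding + Gaussian noise),
and emits conformer ensembles and scrambled-assignment test cases.

The surrogate targets the qualitative shift regularities of conjugated
trienes — inside protons of Z-configured units strongly deshielded, terminal
=CH2 protons the most shielded olefinics — not ppm-exact reproduction of DFT
shieldings.  Base increments were calibrated once against literature
hexatriene/octatriene shift tables and are frozen as defaults.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .models import (
    AssignmentMap,
    Atom,
    ConformerRecord,
    EnsembleShiftSet,
    ExperimentalShiftSet,
    GeometrySpecError,
    ProtonSite,
)
from .steric import hh_distances

BOND_CC_DOUBLE = 1.34
BOND_CC_CONJ = 1.46
BOND_CC_SP3 = 1.53
BOND_CH = 1.09
ANGLE_SP2 = 120.0
ANGLE_SP3 = 111.0
ANGLE_HCH_SP3 = 107.8


@dataclass(frozen=True)
class TrieneSpec:
    """Connectivity of a conjugated triene chain.

    ``pattern`` gives the E/Z configuration of the three conjugated double
    bonds in chain order; ``chain_lengths`` the number of saturated carbons
    before and after the conjugated unit (0 means a terminal =CH2);
    ``torsions`` overrides rotatable-bond dihedrals by name ("C2-C3" style,
    1-based carbons; skew = +120, skew' = -120, syn = 0).
    """

    pattern: tuple[str, str, str]
    chain_lengths: tuple[int, int] = (0, 0)
    torsions: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.pattern) != 3 or any(p not in ("E", "Z") for p in self.pattern):
            raise GeometrySpecError(
                f"pattern must be three E/Z labels, got {self.pattern!r}"
            )
        if any(n < 0 for n in self.chain_lengths):
            raise GeometrySpecError("chain lengths must be non-negative")


@dataclass(frozen=True)
class SurrogateParams:
    """Parameters of the surrogate shielding model (all shifts in ppm).

    sigma_ref plays the role of the TMS reference shielding; the base values
    are typical 1H shifts per proton type; increment_gem is the additive
    deshielding of an olefinic proton whose geminal partner is replaced by
    alkyl; a_s is the r**-6 steric constant in ppm*A^6.
    """

    sigma_ref: float = 31.8
    delta_base_olefinic: float = 5.90
    delta_base_CH2_terminal: float = 5.15
    increment_gem: float = 0.45
    delta_base_allylic: float = 2.00
    delta_base_methylene: float = 1.35
    delta_base_methyl: float = 0.95
    a_s: float = 25.0
    steric_cutoff: float = 3.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


# ---------------------------------------------------------------------------
# Internal-coordinate geometry construction
# ---------------------------------------------------------------------------

def _normalize(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def place_atom(a, b, c, bond: float, angle: float, dihedral: float) -> np.ndarray:
    """Position d with |cd| = bond, angle(b,c,d) = angle, dihedral(a,b,c,d)."""
    angle_r = math.radians(angle)
    dihedral_r = math.radians(dihedral)
    bc = _normalize(np.asarray(c) - np.asarray(b))
    n = _normalize(np.cross(np.asarray(b) - np.asarray(a), bc))
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(angle_r),
        bond * math.sin(angle_r) * math.cos(dihedral_r),
        bond * math.sin(angle_r) * math.sin(dihedral_r),
    ])
    return np.asarray(c) + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def measure_dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle (degrees, IUPAC convention, (-180, 180])."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1n = _normalize(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    angle = math.degrees(math.atan2(y, x))
    return 180.0 if abs(angle + 180.0) < 1e-9 else angle


@dataclass
class TrieneGeometry:
    """Built geometry with bond list, proton typing and site definitions."""

    atoms: list[Atom]
    bonds: list[tuple[int, int]]
    n_carbons: int
    h_by_carbon: dict[int, list[int]]
    h_types: dict[int, str]
    sites: list[ProtonSite]
    torsions: dict[str, float]
    spec: TrieneSpec

    def coords(self) -> np.ndarray:
        return np.array([[x, y, z] for _, x, y, z in self.atoms])

    def hydrogen_indices(self) -> list[int]:
        return [i + 1 for i, a in enumerate(self.atoms) if a[0] == "H"]


def _backbone_plan(spec: TrieneSpec):
    """Per-carbon hybridization and per-bond kind/default dihedral."""
    n_head, n_tail = spec.chain_lengths
    n = n_head + 6 + n_tail
    sp2 = {k: n_head < k <= n_head + 6 for k in range(1, n + 1)}
    double_start = {n_head + 1, n_head + 3, n_head + 5}

    def bond_kind(i: int) -> str:  # bond between carbons i and i+1
        if i in double_start:
            return "double"
        if sp2[i] and sp2[i + 1]:
            return "conj_single"
        return "sp3_single"

    def bond_length(i: int) -> float:
        return {"double": BOND_CC_DOUBLE, "conj_single": BOND_CC_CONJ,
                "sp3_single": BOND_CC_SP3}[bond_kind(i)]

    def default_dihedral(i: int) -> float:  # torsion about bond (i, i+1)
        kind = bond_kind(i)
        if kind == "double":
            db_index = sorted(double_start).index(i)
            return 180.0 if spec.pattern[db_index] == "E" else 0.0
        return 180.0  # s-trans conjugated singles, anti-zigzag sp3 chain

    rotatable = {
        f"C{i}-C{i + 1}"
        for i in range(2, n - 1)
        if bond_kind(i) != "double"
    }
    return n, sp2, bond_kind, bond_length, default_dihedral, rotatable


def build_triene_geometry(spec: TrieneSpec) -> TrieneGeometry:
    """Idealized 3-D geometry of a conjugated triene from internal coordinates.

    Bond lengths: C=C 1.34 A, conjugated C-C 1.46 A, saturated C-C 1.53 A,
    C-H 1.09 A; angles 120 deg at sp2 and 111 deg at sp3 carbons.  Conjugated
    double-bond torsions are 180 deg (E) or 0 deg (Z); conjugated single
    bonds default to s-trans (180 deg); saturated-chain bonds default to
    anti (180 deg).  ``spec.torsions`` overrides any rotatable bond.
    """
    n, sp2, bond_kind, bond_length, default_dihedral, rotatable = _backbone_plan(spec)
    unknown = sorted(set(spec.torsions) - rotatable)
    if unknown:
        raise GeometrySpecError(
            f"torsions {unknown} name non-rotatable or non-existent bonds; "
            f"rotatable bonds: {sorted(rotatable)}"
        )

    def torsion_value(i: int) -> float:
        return float(spec.torsions.get(f"C{i}-C{i + 1}", default_dihedral(i)))

    def angle_at(k: int) -> float:
        return ANGLE_SP2 if sp2[k] else ANGLE_SP3

    carbons = [np.zeros(3), np.array([bond_length(1), 0.0, 0.0])]
    if n >= 3:
        carbons.append(place_atom(
            np.array([0.0, 1.0, 0.0]), carbons[0], carbons[1],
            bond_length(2), angle_at(2), 0.0,
        ))
    for k in range(4, n + 1):
        carbons.append(place_atom(
            carbons[k - 4], carbons[k - 3], carbons[k - 2],
            bond_length(k - 1), angle_at(k - 1), torsion_value(k - 2),
        ))

    atoms: list[Atom] = [("C", *map(float, p)) for p in carbons]
    bonds = [(i, i + 1) for i in range(1, n)]
    h_by_carbon: dict[int, list[int]] = {}
    h_types: dict[int, str] = {}

    def add_h(carbon_k: int, pos: np.ndarray, h_type: str) -> int:
        atoms.append(("H", *map(float, pos)))
        index = len(atoms)
        bonds.append((carbon_k, index))
        h_by_carbon.setdefault(carbon_k, []).append(index)
        h_types[index] = h_type
        return index

    conj_first, conj_last = spec.chain_lengths[0] + 1, spec.chain_lengths[0] + 6
    for k in range(1, n + 1):
        pos = carbons[k - 1]
        prev_c = carbons[k - 2] if k > 1 else None
        next_c = carbons[k] if k < n else None
        if sp2[k]:
            if prev_c is not None and next_c is not None:
                u1 = _normalize(prev_c - pos)
                u2 = _normalize(next_c - pos)
                h_type = ("olefinic_gem" if k in (conj_first, conj_last)
                          else "olefinic")
                add_h(k, pos + BOND_CH * _normalize(-(u1 + u2)), h_type)
            else:
                # terminal =CH2: both H in the sp2 plane, cis/trans to C_ref
                neighbor = next_c if prev_c is None else prev_c
                ref = carbons[2] if prev_c is None else carbons[n - 3]
                for suffix, dihedral in (("a", 0.0), ("b", 180.0)):
                    add_h(k, place_atom(ref, neighbor, pos, BOND_CH,
                                        ANGLE_SP2, dihedral),
                          "olefinic_terminal")
        else:
            allylic = (sp2.get(k - 1, False) or sp2.get(k + 1, False))
            if prev_c is not None and next_c is not None:
                u1 = _normalize(prev_c - pos)
                u2 = _normalize(next_c - pos)
                bisector = _normalize(-(u1 + u2))
                perp = _normalize(np.cross(u1, u2))
                half = math.radians(ANGLE_HCH_SP3 / 2.0)
                h_type = "allylic" if allylic else "methylene"
                for sign in (+1.0, -1.0):
                    add_h(k, pos + BOND_CH * _normalize(
                        bisector * math.cos(half) + sign * perp * math.sin(half)
                    ), h_type)
            else:
                neighbor = next_c if prev_c is None else prev_c
                ref = carbons[2] if prev_c is None else carbons[n - 3]
                h_type = "allylic" if allylic else "methyl"
                for dihedral in (60.0, 180.0, 300.0):
                    add_h(k, place_atom(ref, neighbor, pos, BOND_CH,
                                        ANGLE_SP3, dihedral), h_type)

    sites = []
    for k in range(1, n + 1):
        hs = h_by_carbon.get(k, [])
        if not hs:
            continue
        if sp2[k] and len(hs) == 2:
            for h_index, suffix in zip(hs, ("a", "b")):
                sites.append(ProtonSite(label=f"H{k}{suffix}",
                                        atom_indices=frozenset({h_index})))
        else:
            sites.append(ProtonSite(label=f"H{k}", atom_indices=frozenset(hs)))

    torsions = {}
    for name in sorted(rotatable):
        i = int(name.split("-")[0][1:])
        torsions[name] = measure_dihedral(
            carbons[i - 2], carbons[i - 1], carbons[i], carbons[i + 1]
        )

    return TrieneGeometry(
        atoms=atoms, bonds=bonds, n_carbons=n, h_by_carbon=h_by_carbon,
        h_types=h_types, sites=sites, torsions=torsions, spec=spec,
    )


# ---------------------------------------------------------------------------
# Surrogate shieldings
# ---------------------------------------------------------------------------

def _base_shift(h_type: str, params: SurrogateParams) -> float:
    table = {
        "olefinic": params.delta_base_olefinic,
        "olefinic_terminal": params.delta_base_CH2_terminal,
        "olefinic_gem": params.delta_base_CH2_terminal + params.increment_gem,
        "allylic": params.delta_base_allylic,
        "methylene": params.delta_base_methylene,
        "methyl": params.delta_base_methyl,
    }
    return table[h_type]


def surrogate_shieldings(
    geometry: TrieneGeometry,
    params: SurrogateParams = SurrogateParams(),
    rng: Optional[np.random.Generator] = None,
) -> dict[int, float]:
    """Per-proton isotropic shieldings from the additive surrogate model.

    sigma_H = sigma_ref - delta(type) - sum_pairs a_s / r**6 + N(0, noise_sd),
    the steric sum running over non-bonded H...H pairs (>= 4 covalent bonds
    apart, r <= steric_cutoff).  Deterministic for a fixed seed.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    hydrogens = geometry.hydrogen_indices()
    for h in hydrogens:
        if h not in geometry.h_types:
            raise GeometrySpecError(f"hydrogen atom {h} has no assigned type")
    delta = {h: _base_shift(geometry.h_types[h], params) for h in hydrogens}
    for (i, j), r in hh_distances(geometry.atoms, "auto", bonds=geometry.bonds,
                                  cutoff=params.steric_cutoff):
        contribution = params.a_s / r**6
        delta[i] += contribution
        delta[j] += contribution
    noise = rng.normal(0.0, params.noise_sd, size=len(hydrogens)) if params.noise_sd > 0 else np.zeros(len(hydrogens))
    return {
        h: float(params.sigma_ref - delta[h] + eps)
        for h, eps in zip(hydrogens, noise)
    }


Wells = Union[Sequence[tuple[float, float]], Mapping[str, Sequence[tuple[float, float]]]]


def generate_ensemble(
    spec: TrieneSpec,
    torsional_wells: Wells,
    params: SurrogateParams = SurrogateParams(),
) -> list[ConformerRecord]:
    """Conformer ensemble from enumerated torsional wells.

    ``torsional_wells`` maps torsion name -> list of (angle_deg, depth_kcal)
    wells; a plain list is shorthand for the first rotatable bond.  One
    conformer is produced per element of the well product, with dG the sum of
    the well depths re-zeroed to the minimum, geometry built at the well
    angles, and surrogate shieldings attached (one seeded stream per call).
    """
    probe = build_triene_geometry(spec)
    if not isinstance(torsional_wells, Mapping):
        if not probe.torsions:
            raise GeometrySpecError("molecule has no rotatable bonds")
        torsional_wells = {sorted(probe.torsions)[0]: list(torsional_wells)}
    for name, wells in torsional_wells.items():
        if name not in probe.torsions:
            raise GeometrySpecError(f"unknown rotatable bond {name!r}")
        if not wells:
            raise GeometrySpecError(f"no wells given for {name!r}")

    names = sorted(torsional_wells)
    rng = np.random.default_rng(params.seed)
    combos = list(itertools.product(*(torsional_wells[n] for n in names)))
    total_depths = [sum(depth for _, depth in combo) for combo in combos]
    zero = min(total_depths)

    records = []
    child_rngs = rng.spawn(len(combos))
    for index, (combo, depth, child) in enumerate(zip(combos, total_depths, child_rngs)):
        torsions = dict(spec.torsions)
        torsions.update({name: angle for name, (angle, _) in zip(names, combo)})
        conf_spec = TrieneSpec(pattern=spec.pattern,
                               chain_lengths=spec.chain_lengths,
                               torsions=torsions)
        geometry = build_triene_geometry(conf_spec)
        sigma = surrogate_shieldings(geometry, params, rng=child)
        label = chr(ord("A") + index) if index < 26 else f"conf{index}"
        records.append(ConformerRecord(
            conformer_id=label,
            dG_rel=float(depth - zero),
            torsions=dict(geometry.torsions),
            geometry=list(geometry.atoms),
            shieldings=sigma,
        ))
    return records


def make_torsion_scan(
    gap_kcal: float = 2.37,
    secondary_angle: float = 40.0,
    curvature: float = 0.002,
    step: float = 10.0,
) -> list["TorsionScanPoint"]:
    """Two-well synthetic torsion scan of a conjugated-backbone bond.

    The global minimum sits at 180 deg (planar s-trans) and a secondary
    minimum ``gap_kcal`` higher near ``secondary_angle``; wells are parabolic
    with the given curvature (kcal/mol/deg^2).  The inside-proton shift rises
    from a flat plateau near 180 deg to a strong-deshielding maximum at
    0 deg, the way short H...H contacts switch on as the backbone folds.
    """
    from .models import TorsionScanPoint

    points = []
    angle = 0.0
    while angle <= 180.0 + 1e-9:
        e = min(gap_kcal + curvature * (angle - secondary_angle) ** 2,
                curvature * (angle - 180.0) ** 2)
        shifts = {
            "H_inside": 6.30 + 1.02 * math.exp(-((angle / 45.0) ** 2)),
            "H_outside": 5.90 + 0.10 * math.exp(-((angle / 60.0) ** 2)),
        }
        points.append(TorsionScanPoint(angle=angle, dE_rel=e, dG_rel=e,
                                       site_shifts=shifts))
        angle += step
    return points


def make_revision_case(
    n_sites: int = 8,
    scramble_group: Optional[Sequence[str]] = None,
    noise_sd: float = 0.05,
    seed: int = 0,
    slope: float = 0.95,
    intercept: float = 0.10,
) -> tuple[EnsembleShiftSet, ExperimentalShiftSet, AssignmentMap]:
    """Scrambled-assignment test case with known ground truth.

    Calculated shifts are evenly spread over the olefinic window
    5.4-6.8 ppm; experimental shifts are an affine image plus Gaussian noise,
    with the labels inside ``scramble_group`` permuted by a seeded
    non-identity permutation.  Returns (calc, exp, truth map); applying the
    truth map to the experimental labels restores the planted pairing.
    """
    if n_sites < 3:
        raise ValueError("need at least 3 sites")
    rng = np.random.default_rng(seed)
    labels = [f"H{i}" for i in range(1, n_sites + 1)]
    values = np.linspace(5.4, 6.8, n_sites)
    calc = {lab: float(v) for lab, v in zip(labels, values)}

    if scramble_group is None:
        scramble_group = labels[: min(4, n_sites)]
    scramble_group = list(scramble_group)
    if len(scramble_group) < 2 or not set(scramble_group) <= set(labels):
        raise ValueError("scramble_group must be >= 2 known site labels")

    exp_true = {
        lab: slope * calc[lab] + intercept + float(rng.normal(0.0, noise_sd))
        for lab in labels
    }
    while True:
        perm = rng.permutation(len(scramble_group))
        if any(perm[i] != i for i in range(len(perm))):
            break
    exp_shifts = dict(exp_true)
    truth_mapping = {lab: lab for lab in labels}
    for i, src in enumerate(scramble_group):
        dst = scramble_group[perm[i]]
        exp_shifts[dst] = exp_true[src]
        truth_mapping[src] = dst

    group = [frozenset(scramble_group)]
    truth = AssignmentMap.from_permutation(truth_mapping, group)
    calc_set = EnsembleShiftSet(molecule_id="synthetic", shifts=calc,
                                weights_used={"synthetic": 1.0})
    exp_set = ExperimentalShiftSet(molecule_id="synthetic", solvent="other",
                                   shifts=exp_shifts, source="synthetic")
    return calc_set, exp_set, truth
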