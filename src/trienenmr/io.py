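"""Readers and writers for conformer tables, XYZ geometries, shielding logs,
torsion scans — and the packaged literature fixtures.

File conventions (all plain text):

* conformer table: CSV with header
  ``conformer_id,dG_rel_kcal,dE_rel_kcal,degeneracy,torsion:<name>...,shielding:<atomindex>...``
  Optional cells may be empty.  Energies with a negative minimum are
  interpreted as absolute values in hartree, converted with
  627.5095 kcal/mol per hartree and re-zeroed to the ensemble minimum.
* geometry: standard XYZ (count line, comment line, ``element x y z`` in A).
* shielding log: free text; lines matching
  ``<index> <element> Isotropic = <value>`` carry one shielding each, later
  duplicates override earlier ones with a logged warning.
"""

from __future__ import annotations

import csv
import logging
import re
from importlib import resources
from pathlib import Path
from typing import Iterable, Union

import pandas as pd

from .models import (
    Atom,
    ConformerRecord,
    ExperimentalShiftSet,
    FixtureLookupError,
    ProtonSite,
    SchemaError,
    ShieldingLogError,
    TorsionScanPoint,
    validate_ensemble,
)

logger = logging.getLogger(__name__)

HARTREE_TO_KCAL = 627.5095

_MANDATORY_COLUMNS = ("conformer_id", "dG_rel_kcal")


def _rezero_energies(values: list[float | None]) -> list[float | None]:
    """Re-zero an energy column to its minimum.

    Columns whose minimum is negative are taken to hold absolute energies in
    hartree and are converted to relative kcal/mol; already-relative kcal/mol
    columns (minimum at zero) pass through unchanged.  Idempotent.
    """
    present = [v for v in values if v is not None]
    if not present:
        return values
    lo = min(present)
    if lo >= 0:  # already relative kcal/mol: leave verbatim
        return values
    return [None if v is None else (v - lo) * HARTREE_TO_KCAL for v in values]


def read_conformer_table(path: Union[str, Path]) -> list[ConformerRecord]:
    """Read conformer records from the conformer-table CSV schema."""
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError(f"{path}: empty file") from None
        rows = list(reader)

    header = [h.strip() for h in header]
    for col in _MANDATORY_COLUMNS:
        if col not in header:
            raise SchemaError(f"{path}: missing mandatory column {col!r}")
    idx = {name: i for i, name in enumerate(header)}
    torsion_cols = [(h[len("torsion:"):], i) for i, h in enumerate(header) if h.startswith("torsion:")]
    shield_cols = [(int(h[len("shielding:"):]), i) for i, h in enumerate(header) if h.startswith("shielding:")]

    def cell(row: list[str], i: int) -> str:
        return row[i].strip() if i < len(row) else ""

    def number(row: list[str], i: int, lineno: int, col: str) -> float | None:
        text = cell(row, i)
        if text == "":
            return None
        try:
            return float(text)
        except ValueError:
            raise SchemaError(
                f"{path}:{lineno}: non-numeric value {text!r} in column {col!r}"
            ) from None

    ids, dgs, des, rest = [], [], [], []
    for lineno, row in enumerate(rows, start=2):
        if not any(c.strip() for c in row):
            continue
        cid = cell(row, idx["conformer_id"])
        dg = number(row, idx["dG_rel_kcal"], lineno, "dG_rel_kcal")
        if dg is None:
            raise SchemaError(f"{path}:{lineno}: empty dG_rel_kcal for {cid!r}")
        de = number(row, idx["dE_rel_kcal"], lineno, "dE_rel_kcal") if "dE_rel_kcal" in idx else None
        deg_raw = number(row, idx["degeneracy"], lineno, "degeneracy") if "degeneracy" in idx else None
        degeneracy = 1 if deg_raw is None else int(deg_raw)
        torsions = {}
        for name, i in torsion_cols:
            v = number(row, i, lineno, f"torsion:{name}")
            if v is not None:
                torsions[name] = v
        shieldings = {}
        for atom_idx, i in shield_cols:
            v = number(row, i, lineno, f"shielding:{atom_idx}")
            if v is not None:
                shieldings[atom_idx] = v
        ids.append(cid)
        dgs.append(dg)
        des.append(de)
        rest.append((degeneracy, torsions, shieldings))

    dgs = _rezero_energies(dgs)
    des = _rezero_energies(des)
    records = [
        ConformerRecord(
            conformer_id=cid, dG_rel=dg, dE_rel=de,
            degeneracy=deg, torsions=tor, shieldings=sh,
        )
        for cid, dg, de, (deg, tor, sh) in zip(ids, dgs, des, rest)
    ]
    validate_ensemble(records)
    return records


def write_conformer_table(records: Iterable[ConformerRecord], path: Union[str, Path]) -> None:
    """Write records in the conformer-table CSV schema (full float precision)."""
    records = list(records)
    torsion_names = sorted({n for r in records for n in r.torsions})
    atom_indices = sorted({i for r in records for i in r.shieldings})
    header = ["conformer_id", "dG_rel_kcal", "dE_rel_kcal", "degeneracy"]
    header += [f"torsion:{n}" for n in torsion_names]
    header += [f"shielding:{i}" for i in atom_indices]
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for r in records:
            row = [
                r.conformer_id,
                repr(r.dG_rel),
                "" if r.dE_rel is None else repr(r.dE_rel),
                str(r.degeneracy),
            ]
            row += ["" if n not in r.torsions else repr(r.torsions[n]) for n in torsion_names]
            row += ["" if i not in r.shieldings else repr(r.shieldings[i]) for i in atom_indices]
            writer.writerow(row)


_SHIELDING_RE = re.compile(
    r"^\s*(\d+)\s+([A-Za-z]{1,2})\s+Isotropic\s*=\s*(-?\d+(?:\.\d+)?)\s*$"
)


def read_shielding_log(path: Union[str, Path], dialect: str = "minimal_giao") -> dict[int, float]:
    """Extract isotropic shieldings from the minimal GIAO log dialect.

    Lines matching ``<index> <element> Isotropic = <value>`` are kept; all
    other lines are ignored.  A later entry for the same atom index overrides
    the earlier one with a logged warning.
    """
    if dialect != "minimal_giao":
        raise ValueError(f"unknown shielding-log dialect {dialect!r}")
    path = Path(path)
    shieldings: dict[int, float] = {}
    for line in path.read_text().splitlines():
        m = _SHIELDING_RE.match(line)
        if not m:
            continue
        index = int(m.group(1))
        value = float(m.group(3))
        if index in shieldings:
            logger.warning(
                "%s: duplicate shielding for atom %d (%.4f overrides %.4f)",
                path, index, value, shieldings[index],
            )
        shieldings[index] = value
    if not shieldings:
        raise ShieldingLogError(f"{path}: no isotropic-shielding lines found")
    return shieldings


def write_shielding_log(shieldings: dict[int, float], path: Union[str, Path],
                        element: str = "H") -> None:
    """Emit a minimal GIAO-dialect log (round-trips with read_shielding_log)."""
    lines = ["-- synthetic isotropic shieldings --"]
    for index in sorted(shieldings):
        lines.append(f"{index:7d}  {element}    Isotropic = {shieldings[index]:12.4f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_xyz(path: Union[str, Path]) -> list[Atom]:
    """Read a single-frame XYZ file (count line, comment, element x y z)."""
    lines = Path(path).read_text().splitlines()
    if len(lines) < 2:
        raise SchemaError(f"{path}: truncated XYZ file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise SchemaError(f"{path}: first line of XYZ must be the atom count") from None
    atoms: list[Atom] = []
    for lineno, line in enumerate(lines[2:2 + n], start=3):
        parts = line.split()
        if len(parts) < 4:
            raise SchemaError(f"{path}:{lineno}: expected 'element x y z'")
        atoms.append((parts[0], float(parts[1]), float(parts[2]), float(parts[3])))
    if len(atoms) != n:
        raise SchemaError(f"{path}: header says {n} atoms, found {len(atoms)}")
    return atoms


def write_xyz(atoms: list[Atom], path: Union[str, Path], comment: str = "") -> None:
    lines = [str(len(atoms)), comment.replace("\n", " ")]
    for el, x, y, z in atoms:
        lines.append(f"{el:2s} {x:15.8f} {y:15.8f} {z:15.8f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_experimental_csv(path: Union[str, Path], molecule_id: str = "",
                          solvent: str = "CHCl3", source: str = "") -> ExperimentalShiftSet:
    """Read an experimental shift table CSV with columns site,delta_exp_ppm.

    Optional molecule_id/solvent/source columns override the arguments.
    """
    df = pd.read_csv(path)
    if "site" not in df.columns or "delta_exp_ppm" not in df.columns:
        raise SchemaError(f"{path}: need columns 'site' and 'delta_exp_ppm'")
    if "molecule_id" in df.columns and len(df):
        molecule_id = str(df["molecule_id"].iloc[0])
    if "solvent" in df.columns and len(df):
        solvent = str(df["solvent"].iloc[0])
    if "source" in df.columns and len(df):
        source = str(df["source"].iloc[0])
    shifts = dict(zip(df["site"].astype(str), df["delta_exp_ppm"].astype(float)))
    if len(shifts) != len(df):
        raise SchemaError(f"{path}: duplicate site labels")
    return ExperimentalShiftSet(molecule_id=molecule_id, solvent=solvent,
                                shifts=shifts, source=source)


def write_experimental_csv(exp: ExperimentalShiftSet, path: Union[str, Path]) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["molecule_id", "solvent", "site", "delta_exp_ppm", "source"])
        for site, delta in exp.shifts.items():
            writer.writerow([exp.molecule_id, exp.solvent, site, repr(delta), exp.source])


def read_sites_csv(path: Union[str, Path], molecule_id: str = "") -> list[ProtonSite]:
    """Read proton sites from a CSV with columns site,atom_indices.

    ``atom_indices`` is a semicolon-separated list of 1-based atom indices.
    """
    df = pd.read_csv(path)
    if "site" not in df.columns or "atom_indices" not in df.columns:
        raise SchemaError(f"{path}: need columns 'site' and 'atom_indices'")
    sites = []
    for _, row in df.iterrows():
        indices = frozenset(int(tok) for tok in str(row["atom_indices"]).split(";") if tok.strip())
        sites.append(ProtonSite(label=str(row["site"]), atom_indices=indices,
                                molecule_id=molecule_id))
    return sites


def read_torsion_scan(path: Union[str, Path]) -> list[TorsionScanPoint]:
    """Read a torsion scan CSV: ``angle_deg,dE_kcal,dG_kcal,shift:<site>...``."""
    df = pd.read_csv(path)
    if "angle_deg" not in df.columns or "dE_kcal" not in df.columns:
        raise SchemaError(f"{path}: need columns 'angle_deg' and 'dE_kcal'")
    shift_cols = [c for c in df.columns if c.startswith("shift:")]
    points = []
    for _, row in df.iterrows():
        dg = row.get("dG_kcal")
        dg = None if dg is None or pd.isna(dg) else float(dg)
        shifts = {c[len("shift:"):]: float(row[c]) for c in shift_cols if pd.notna(row[c])}
        points.append(TorsionScanPoint(angle=float(row["angle_deg"]),
                                       dE_rel=float(row["dE_kcal"]),
                                       dG_rel=dg, site_shifts=shifts))
    return points


def write_torsion_scan(points: list[TorsionScanPoint], path: Union[str, Path]) -> None:
    sites = sorted({s for p in points for s in p.site_shifts})
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["angle_deg", "dE_kcal", "dG_kcal"] + [f"shift:{s}" for s in sites])
        for p in points:
            row = [repr(p.angle), repr(p.dE_rel),
                   "" if p.dG_rel is None else repr(p.dG_rel)]
            row += ["" if s not in p.site_shifts else repr(p.site_shifts[s]) for s in sites]
            writer.writerow(row)


# ---------------------------------------------------------------------------
# Packaged literature fixtures
# ---------------------------------------------------------------------------

def _data_path(name: str):
    return resources.files("trienenmr.data").joinpath(name)


def load_experimental_shifts() -> dict[str, ExperimentalShiftSet]:
    """All packaged experimental 1H shift tables, keyed by molecule id."""
    with resources.as_file(_data_path("table1_shifts.csv")) as p:
        df = pd.read_csv(p)
    out: dict[str, ExperimentalShiftSet] = {}
    for mol, grp in df.groupby("molecule_id", sort=False):
        out[str(mol)] = ExperimentalShiftSet(
            molecule_id=str(mol),
            solvent=str(grp["solvent"].iloc[0]),
            shifts=dict(zip(grp["site"].astype(str), grp["delta_exp_ppm"].astype(float))),
            source=str(grp["source"].iloc[0]),
        )
    return out


def load_conformer_energies() -> pd.DataFrame:
    """The packaged conformer free-energy table (all isomers and methods).

    Columns: isomer, common_name, method, conformer, phi1_deg, phi1_label,
    phi2_deg, phi2_label, dG_kcal, population_pct (the literature-printed
    population, kept verbatim for cross-checking).
    """
    with resources.as_file(_data_path("table2_conformers.csv")) as p:
        return pd.read_csv(p)


def conformer_records(isomer: str, method: str = "B3LYP") -> tuple[list[ConformerRecord], dict[str, float]]:
    """Conformer records plus printed populations for one isomer/method.

    Returns ``(records, printed_populations_pct)``; raises FixtureLookupError
    for unknown keys.
    """
    df = load_conformer_energies()
    sel = df[(df["isomer"] == isomer) & (df["method"] == method)]
    if sel.empty:
        valid = sorted(df["isomer"].unique())
        raise FixtureLookupError(
            f"no fixture rows for isomer={isomer!r} method={method!r}; "
            f"valid isomers: {valid}, methods: ['B3LYP', 'APFD']"
        )
    records = []
    for _, row in sel.iterrows():
        torsions = {}
        if pd.notna(row["phi1_deg"]):
            torsions["phi_C7C8C9C10"] = float(row["phi1_deg"])
        if pd.notna(row["phi2_deg"]):
            torsions["phi_C13C14C15C16"] = float(row["phi2_deg"])
        records.append(ConformerRecord(
            conformer_id=str(row["conformer"]),
            dG_rel=float(row["dG_kcal"]),
            torsions=torsions,
        ))
    printed = dict(zip(sel["conformer"].astype(str), sel["population_pct"].astype(float)))
    validate_ensemble(records)
    return records, printed


def load_literature_fixtures(name: str):
    """Dispatch to a packaged fixture: 'table1' (experimental shifts) or
    'table2' (conformer energies)."""
    loaders = {"table1": load_experimental_shifts, "table2": load_conformer_energies}
    if name not in loaders:
        raise FixtureLookupError(
            f"unknown fixture {name!r}; valid names: {sorted(loaders)}"
        )
    return loaders[name]()
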