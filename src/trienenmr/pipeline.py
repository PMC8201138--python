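"""End-to-end orchestration: config, stage wiring, machine-readable reports.

Every run writes JSON/CSV reports stamped with a provenance block (package
version, seed, SHA-256 hash of the resolved config) so that identical inputs
yield bit-identical outputs; floats are serialized at fixed 1e-6 ppm
precision for that reason.  Logging goes to standard error, results only to
files or standard output.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping, Optional, Union

import yaml

from . import __version__
from .assignment import SwapSearchSpec, candidates_to_rows, optimize_assignment, revision_report
from .ensemble import WeightingSpec, boltzmann_populations, ensemble_site_shifts
from .io import (
    read_conformer_table,
    read_experimental_csv,
    read_sites_csv,
)
from .models import AssignmentMap, InsufficientDataError
from .regression import compare_reports, fit_linear, scaled_shifts

logger = logging.getLogger(__name__)

POPULATION_CONSISTENCY_PP = 0.02   # percentage points per conformer
POPULATION_SUM_SLACK_PCT = 0.05    # tolerated deviation of a printed sum from 100


@dataclass
class RunConfig:
    """Inputs and options for a full analysis run."""

    conformer_table: Optional[str] = None
    experimental_csv: Optional[str] = None
    sites_csv: Optional[str] = None
    output_dir: str = "trienenmr_out"
    temperature_K: float = 298.15
    energy_kind: str = "free_energy"
    sigma_ref_ppm: float = 31.8
    solvent: str = "CHCl3"
    regression_orientation: str = "calc_on_exp"
    revise: bool = True
    swap_window_ppm: float = 0.10
    swap_groups: Optional[list[list[str]]] = None
    swap_objective: str = "max_r2"
    max_permutations: int = 10**6
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def weighting(self) -> WeightingSpec:
        return WeightingSpec(temperature=self.temperature_K, energy_kind=self.energy_kind)

    def swap_spec(self) -> SwapSearchSpec:
        groups = None
        if self.swap_groups:
            groups = tuple(frozenset(g) for g in self.swap_groups)
        return SwapSearchSpec(
            exchange_groups=groups,
            auto_window=None if groups else self.swap_window_ppm,
            objective=self.swap_objective,
            max_permutations=self.max_permutations,
        )

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _round_floats(obj: Any, ndigits: int = 6) -> Any:
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def provenance(config: RunConfig) -> dict:
    return {
        "package": "trienenmr",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
    }


def write_json(payload: Mapping, path: Union[str, Path], config: RunConfig) -> None:
    body = dict(payload)
    body["provenance"] = provenance(config)
    Path(path).write_text(
        json.dumps(_round_floats(body), indent=2, sort_keys=True) + "\n"
    )


def check_population_consistency(
    computed_pct: Mapping[str, float], reference_pct: Mapping[str, float]
) -> dict:
    """Compare computed percentages against a printed reference column.

    Flags the row as inconsistent when any conformer deviates by more than
    0.02 percentage points, or the reference column does not itself sum to
    100 % (incomplete conformer list).
    """
    deviations = {
        cid: float(computed_pct[cid] - reference_pct[cid])
        for cid in reference_pct
        if cid in computed_pct
    }
    max_dev = max((abs(v) for v in deviations.values()), default=float("nan"))
    ref_sum = float(sum(reference_pct.values()))
    complete = abs(ref_sum - 100.0) <= POPULATION_SUM_SLACK_PCT
    consistent = complete and max_dev <= POPULATION_CONSISTENCY_PP
    return {
        "self_consistent": bool(consistent),
        "reference_complete": bool(complete),
        "reference_sum_pct": ref_sum,
        "max_abs_deviation_pp": float(max_dev),
        "deviations_pp": deviations,
    }


def run_populations(
    config: RunConfig,
    reference_pct: Optional[Mapping[str, float]] = None,
) -> dict:
    """Boltzmann populations from the configured conformer table.

    Writes populations.csv and populations.json to the output directory and
    returns the JSON payload.  When a reference column is supplied the
    self-consistency check is attached instead of silently matching.
    """
    if not config.conformer_table:
        raise InsufficientDataError("config.conformer_table is not set")
    records = read_conformer_table(config.conformer_table)
    populations = boltzmann_populations(records, config.weighting())
    pct = {cid: 100.0 * p for cid, p in populations.items()}
    payload: dict[str, Any] = {
        "temperature_K": config.temperature_K,
        "energy_kind": config.energy_kind,
        "populations_pct": pct,
        "sum_pct": float(sum(pct.values())),
    }
    if reference_pct is not None:
        payload["consistency"] = check_population_consistency(pct, reference_pct)

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    with (out / "populations.csv").open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["conformer_id", "dG_rel_kcal", "population_pct", "config_hash"])
        by_id = {r.conformer_id: r for r in records}
        for cid, value in pct.items():
            writer.writerow([cid, repr(by_id[cid].dG_rel), f"{value:.6f}",
                             config.config_hash()])
    write_json(payload, out / "populations.json", config)
    return payload


def run_full(config: RunConfig) -> dict:
    """Populations -> ensemble shifts -> regression -> optional revision.

    Returns the report bundle (also written as bundle.json); each stage's
    intermediate results are included, with stage-tagged errors on failure
    and partial outputs flushed before the error propagates.
    """
    if not (config.conformer_table and config.experimental_csv and config.sites_csv):
        raise InsufficientDataError(
            "run_full needs conformer_table, experimental_csv and sites_csv"
        )
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict[str, Any] = {}

    def flush() -> None:
        write_json(bundle, out / "bundle.json", config)

    stage = "read_inputs"
    try:
        records = read_conformer_table(config.conformer_table)
        exp = read_experimental_csv(config.experimental_csv, solvent=config.solvent)
        sites = read_sites_csv(config.sites_csv, molecule_id=exp.molecule_id)

        stage = "populations"
        populations = boltzmann_populations(records, config.weighting())
        bundle["populations_pct"] = {cid: 100.0 * p for cid, p in populations.items()}

        stage = "ensemble_shifts"
        calc = ensemble_site_shifts(records, sites, config.sigma_ref_ppm,
                                    config.weighting(), molecule_id=exp.molecule_id)
        bundle["calc_shifts_ppm"] = dict(calc.shifts)
        bundle["sigma_ref_ppm"] = config.sigma_ref_ppm

        stage = "regression"
        shared = sorted(set(calc.shifts) & set(exp.shifts))
        calc_shared = {s: calc.shifts[s] for s in shared}
        exp_shared = {s: exp.shifts[s] for s in shared}
        identity_report = fit_linear(calc_shared, exp_shared,
                                     orientation=config.regression_orientation)
        bundle["regression"] = identity_report.to_dict()
        bundle["scaled_shifts_ppm"] = scaled_shifts(identity_report, calc_shared)

        if config.revise:
            stage = "revision"
            best_map, best_report, candidates = optimize_assignment(
                calc_shared, exp_shared, config.swap_spec()
            )
            comparison = compare_reports(identity_report, best_report)
            identity = AssignmentMap.identity(shared)
            text, summary = revision_report(identity, best_map, comparison, exp_shared)
            bundle["revision"] = {
                "summary": summary,
                "text": text,
                "revised_regression": best_report.to_dict(),
                "n_candidates": len(candidates),
            }
            with (out / "revision_candidates.csv").open("w", newline="") as fh:
                rows = candidates_to_rows(candidates)
                writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
                writer.writeheader()
                writer.writerows(rows)
    except Exception:
        logger.exception("stage %r failed", stage)
        bundle["failed_stage"] = stage
        flush()
        raise

    flush()
    return bundle
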