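"""Boltzmann populations, ensemble averaging and TMS referencing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trienenmr.ensemble import (
    WeightingSpec,
    average_equivalent,
    boltzmann_populations,
    ensemble_shieldings,
    ensemble_site_shifts,
    shieldings_to_shifts,
)
from trienenmr.io import conformer_records
from trienenmr.models import (
    ConformerRecord,
    CoverageError,
    InconsistentEnsembleError,
    MissingEnergyError,
    ProtonSite,
)

SELF_CONSISTENT_ROWS = [
    ("9E11E13E", "B3LYP"),
    ("9E11E13E", "APFD"),
    ("9Z11E13E", "B3LYP"),
    ("9Z11E13E", "APFD"),
    ("9Z11E13Z", "APFD"),
    ("10E12E14Z", "B3LYP"),
    ("10E12E14Z", "APFD"),
    ("10E12Z14Z", "B3LYP"),
    ("10E12Z14Z", "APFD"),
]


def _records(dgs, degeneracies=None):
    degeneracies = degeneracies or [1] * len(dgs)
    return [
        ConformerRecord(conformer_id=f"c{i}", dG_rel=g, degeneracy=d)
        for i, (g, d) in enumerate(zip(dgs, degeneracies))
    ]


class TestBoltzmannPopulations:
    @pytest.mark.parametrize("isomer,method", SELF_CONSISTENT_ROWS)
    def test_reproduces_literature_populations(self, isomer, method):
        """Printed percentages recovered within 0.02 pp at 298.15 K."""
        records, printed = conformer_records(isomer, method)
        populations = boltzmann_populations(records)
        for cid, expected_pct in printed.items():
            assert 100.0 * populations[cid] == pytest.approx(expected_pct, abs=0.02)

    def test_two_isoenergetic_conformers_split_evenly(self):
        populations = boltzmann_populations(_records([0.0, 0.0]))
        assert populations == pytest.approx({"c0": 0.5, "c1": 0.5})

    def test_single_conformer_gets_everything(self):
        assert boltzmann_populations(_records([0.0])) == {"c0": 1.0}

    def test_fractions_sum_to_one(self, rng):
        dgs = sorted(rng.uniform(0, 5, size=8))
        dgs[0] = 0.0
        populations = boltzmann_populations(_records(dgs))
        assert sum(populations.values()) == pytest.approx(1.0, abs=1e-12)

    def test_missing_electronic_energy_names_conformer(self):
        records = _records([0.0, 1.0])
        spec = WeightingSpec(energy_kind="electronic")
        with pytest.raises(MissingEnergyError, match="c0"):
            boltzmann_populations(records, spec)

    @settings(deadline=None, max_examples=30)
    @given(
        dgs=st.lists(st.floats(0, 10), min_size=2, max_size=6),
        shift=st.floats(-50, 50),
    )
    def test_invariant_under_constant_energy_shift(self, dgs, shift):
        base = boltzmann_populations(_records(dgs))
        shifted = boltzmann_populations(
            [ConformerRecord(conformer_id=f"c{i}", dG_rel=g + shift)
             for i, g in enumerate(dgs)]
        )
        for cid in base:
            assert shifted[cid] == pytest.approx(base[cid], abs=1e-12)

    def test_monotone_decreasing_in_energy(self, rng):
        dgs = [0.0, 0.5, 1.5, 4.0]
        populations = boltzmann_populations(_records(dgs))
        values = [populations[f"c{i}"] for i in range(4)]
        assert values == sorted(values, reverse=True)

    def test_high_temperature_limit_is_degeneracy_proportional(self):
        records = _records([0.0, 2.0], degeneracies=[1, 3])
        populations = boltzmann_populations(records, WeightingSpec(temperature=1e9))
        assert populations["c1"] == pytest.approx(0.75, abs=1e-6)

    def test_low_temperature_limit_selects_minimum(self):
        populations = boltzmann_populations(
            _records([0.0, 0.2]), WeightingSpec(temperature=1e-3)
        )
        assert populations["c0"] == pytest.approx(1.0, abs=1e-12)


class TestEnsembleShieldings:
    def test_even_weights_give_arithmetic_mean(self):
        records = [
            ConformerRecord("a", 0.0, shieldings={1: 25.0}),
            ConformerRecord("b", 0.0, shieldings={1: 26.0}),
        ]
        sigma = ensemble_shieldings(records, {"a": 0.5, "b": 0.5})
        assert sigma[1] == pytest.approx(25.5)

    def test_dominant_conformer_limit(self):
        records = [
            ConformerRecord("a", 0.0, shieldings={1: 25.0}),
            ConformerRecord("b", 0.0, shieldings={1: 26.0}),
        ]
        sigma = ensemble_shieldings(records, {"a": 0.999, "b": 0.001})
        assert abs(sigma[1] - 25.0) <= 0.001 * 1.0 + 1e-12

    def test_matches_direct_summation_oracle(self, rng):
        atoms = list(range(1, 7))
        weights = rng.dirichlet(np.ones(5))
        records = [
            ConformerRecord(f"c{i}", 0.0,
                            shieldings={a: float(rng.normal(26, 1)) for a in atoms})
            for i in range(5)
        ]
        populations = {f"c{i}": float(w) for i, w in enumerate(weights)}
        sigma = ensemble_shieldings(records, populations)
        for a in atoms:
            oracle = sum(populations[r.conformer_id] * r.shieldings[a] for r in records)
            assert sigma[a] == pytest.approx(oracle, abs=1e-12)

    def test_atom_set_mismatch_lists_indices(self):
        records = [
            ConformerRecord("a", 0.0, shieldings={1: 25.0, 2: 25.0}),
            ConformerRecord("b", 0.0, shieldings={1: 26.0, 3: 26.0}),
        ]
        with pytest.raises(InconsistentEnsembleError, match=r"\[2, 3\]"):
            ensemble_shieldings(records, {"a": 0.5, "b": 0.5})


class TestShiftsAndSites:
    def test_tms_referencing(self):
        assert shieldings_to_shifts({1: 25.0}, 31.8)[1] == pytest.approx(6.8)
        assert shieldings_to_shifts({1: 31.8}, 31.8)[1] == pytest.approx(0.0)

    @given(st.dictionaries(st.integers(1, 50),
                           st.floats(0, 40, allow_nan=False), min_size=2))
    def test_more_shielded_means_smaller_shift(self, sigma):
        shifts = shieldings_to_shifts(sigma, 31.8)
        for a in sigma:
            for b in sigma:
                # strict ordering up to float cancellation in the subtraction
                if sigma[b] - sigma[a] > 1e-9:
                    assert shifts[a] > shifts[b]

    def test_methyl_average_and_passthrough(self):
        atom_shifts = {17: 0.90, 18: 0.92, 19: 0.94, 5: 6.1}
        sites = [
            ProtonSite("H18", frozenset({17, 18, 19})),
            ProtonSite("H5", frozenset({5})),
        ]
        result = average_equivalent(atom_shifts, sites)
        assert result.shifts["H18"] == pytest.approx(0.92)
        assert result.shifts["H5"] == pytest.approx(6.1)

    def test_missing_atom_raises_coverage_error(self):
        with pytest.raises(CoverageError, match=r"\[9\]"):
            average_equivalent({1: 5.0}, [ProtonSite("H9", frozenset({9}))])

    def test_unreferenced_atoms_warn(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="trienenmr.ensemble"):
            average_equivalent({1: 5.0, 2: 6.0}, [ProtonSite("H1", frozenset({1}))])
        assert any("no site" in r.message for r in caplog.records)


def test_weighting_and_referencing_commute(rng):
    """Site shift of the ensemble equals the weighted mean of per-conformer
    site shifts: referencing (an affine map) commutes with averaging."""
    atoms = [1, 2, 3]
    dgs = [0.0, 0.4, 1.1]
    records = [
        ConformerRecord(f"c{i}", g,
                        shieldings={a: float(rng.normal(26, 1)) for a in atoms})
        for i, g in enumerate(dgs)
    ]
    sites = [ProtonSite("X", frozenset({1, 2})), ProtonSite("Y", frozenset({3}))]
    sigma_ref = 31.7
    combined = ensemble_site_shifts(records, sites, sigma_ref)
    populations = boltzmann_populations(records)
    for site in sites:
        per_conformer = [
            np.mean([sigma_ref - r.shieldings[a] for a in site.atom_indices])
            for r in records
        ]
        oracle = sum(populations[r.conformer_id] * d
                     for r, d in zip(records, per_conformer))
        assert combined.shifts[site.label] == pytest.approx(oracle, abs=1e-12)
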