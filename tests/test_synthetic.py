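"""Geometry builder, surrogate shieldings and synthetic case generators."""

import numpy as np
import pytest

from trienenmr.ensemble import boltzmann_populations, ensemble_site_shifts
from trienenmr.models import GeometrySpecError
from trienenmr.regression import fit_linear
from trienenmr.synthetic import (
    BOND_CC_CONJ,
    BOND_CC_DOUBLE,
    BOND_CH,
    SurrogateParams,
    TrieneSpec,
    build_triene_geometry,
    generate_ensemble,
    make_revision_case,
    measure_dihedral,
    surrogate_shieldings,
)


def _site_atom(geometry, label):
    site = next(s for s in geometry.sites if s.label == label)
    return next(iter(site.atom_indices))


def _distance(geometry, i, j):
    coords = geometry.coords()
    return float(np.linalg.norm(coords[i - 1] - coords[j - 1]))


class TestGeometryBuilder:
    def test_all_e_conjugated_torsions_are_trans(self, hexatriene_e):
        coords = hexatriene_e.coords()
        for i in range(2, hexatriene_e.n_carbons - 1):
            dihedral = measure_dihedral(coords[i - 2], coords[i - 1],
                                        coords[i], coords[i + 1])
            assert abs(abs(dihedral) - 180.0) < 1e-9

    def test_idealized_bond_lengths(self, hexatriene_z):
        assert _distance(hexatriene_z, 1, 2) == pytest.approx(BOND_CC_DOUBLE, abs=1e-6)
        assert _distance(hexatriene_z, 2, 3) == pytest.approx(BOND_CC_CONJ, abs=1e-6)
        for carbon, hs in hexatriene_z.h_by_carbon.items():
            for h in hs:
                assert _distance(hexatriene_z, carbon, h) == pytest.approx(
                    BOND_CH, abs=1e-6
                )

    def test_inside_contact_z_versus_e(self, hexatriene_z, hexatriene_e):
        dz = _distance(hexatriene_z, _site_atom(hexatriene_z, "H2"),
                       _site_atom(hexatriene_z, "H5"))
        de = _distance(hexatriene_e, _site_atom(hexatriene_e, "H2"),
                       _site_atom(hexatriene_e, "H5"))
        assert dz < 2.2
        assert de > 3.0

    def test_allylic_torsion_round_trip(self):
        # skew/skew' allylic arrangement of a long-chain triene
        spec = TrieneSpec(pattern=("E", "E", "E"), chain_lengths=(7, 3),
                          torsions={"C7-C8": 120.0, "C14-C15": -120.0})
        geometry = build_triene_geometry(spec)
        assert geometry.torsions["C7-C8"] == pytest.approx(120.0, abs=1e-9)
        assert geometry.torsions["C14-C15"] == pytest.approx(-120.0, abs=1e-9)

    def test_non_rotatable_torsion_rejected(self):
        with pytest.raises(GeometrySpecError, match="C1-C2"):
            build_triene_geometry(TrieneSpec(pattern=("E", "E", "E"),
                                             torsions={"C1-C2": 90.0}))

    def test_bad_pattern_rejected(self):
        with pytest.raises(GeometrySpecError):
            TrieneSpec(pattern=("E", "Q", "E"))

    def test_site_partition_is_disjoint_and_covers_hydrogens(self, hexatriene_z):
        seen = set()
        for site in hexatriene_z.sites:
            assert not (site.atom_indices & seen)
            seen |= site.atom_indices
        assert seen == set(hexatriene_z.hydrogen_indices())


class TestSurrogateShieldings:
    def test_no_interaction_limit_uniform_interior_olefinics(self, hexatriene_z):
        params = SurrogateParams(a_s=0.0, noise_sd=0.0)
        sigma = surrogate_shieldings(hexatriene_z, params)
        interior = [h for h, t in hexatriene_z.h_types.items() if t == "olefinic"]
        expected = params.sigma_ref - params.delta_base_olefinic
        for h in interior:
            assert sigma[h] == pytest.approx(expected, abs=1e-12)

    def test_fixed_seed_is_bit_identical(self, hexatriene_z):
        params = SurrogateParams(noise_sd=0.05, seed=7)
        assert surrogate_shieldings(hexatriene_z, params) == surrogate_shieldings(
            hexatriene_z, params
        )

    def test_z_inside_protons_more_deshielded_than_e(
        self, hexatriene_z, hexatriene_e, quiet_params
    ):
        sigma_z = surrogate_shieldings(hexatriene_z, quiet_params)
        sigma_e = surrogate_shieldings(hexatriene_e, quiet_params)
        for label in ("H2", "H5"):
            hz = _site_atom(hexatriene_z, label)
            he = _site_atom(hexatriene_e, label)
            assert sigma_z[hz] < sigma_e[he]  # smaller sigma = more deshielded

    def test_terminal_ch2_most_shielded_olefinics(self, hexatriene_z, quiet_params):
        sigma = surrogate_shieldings(hexatriene_z, quiet_params)
        terminal = [h for h, t in hexatriene_z.h_types.items()
                    if t == "olefinic_terminal"]
        interior = [h for h, t in hexatriene_z.h_types.items() if t == "olefinic"]
        # larger sigma = more shielded: every =CH2 proton beats every CH
        assert min(sigma[h] for h in terminal) > max(sigma[h] for h in interior)


class TestGenerateEnsemble:
    def test_literature_well_depths_reproduce_populations(self):
        # the five allylic-conformer wells of the all-E C18:3 acid
        wells = [(120.26, 0.36), (120.11, 0.0), (-0.78, 3.00),
                 (-117.53, 1.89), (-0.75, 1.94)]
        spec = TrieneSpec(pattern=("E", "E", "E"), chain_lengths=(7, 3))
        records = generate_ensemble(spec, {"C7-C8": wells},
                                    SurrogateParams(noise_sd=0.0))
        populations = boltzmann_populations(records)
        expected = {"A": 33.41, "B": 61.35, "C": 0.39, "D": 2.53, "E": 2.32}
        for cid, pct in expected.items():
            assert 100.0 * populations[cid] == pytest.approx(pct, abs=0.02)

    def test_single_well_single_conformer(self):
        records = generate_ensemble(TrieneSpec(pattern=("E", "Z", "E")),
                                    [(180.0, 0.0)], SurrogateParams())
        assert len(records) == 1
        assert boltzmann_populations(records) == {"A": 1.0}

    def test_two_equal_wells_split_evenly(self):
        records = generate_ensemble(TrieneSpec(pattern=("E", "Z", "E")),
                                    [(180.0, 0.0), (120.0, 0.0)],
                                    SurrogateParams())
        populations = boltzmann_populations(records)
        assert populations == pytest.approx({"A": 0.5, "B": 0.5})

    def test_records_carry_geometry_and_shieldings(self):
        records = generate_ensemble(TrieneSpec(pattern=("E", "Z", "E")),
                                    [(180.0, 0.0)], SurrogateParams())
        (record,) = records
        assert record.geometry is not None
        assert set(record.shieldings)  # hydrogens present
        assert record.torsions["C2-C3"] == pytest.approx(180.0, abs=1e-9)


def test_end_to_end_ensemble_regression(quiet_params):
    """Ensemble shifts regressed on the surrogate's own noiseless values
    stay essentially perfectly linear at 0.02 ppm noise."""
    spec = TrieneSpec(pattern=("E", "Z", "E"), chain_lengths=(1, 1))
    wells = [(180.0, 0.0), (120.0, 0.8)]
    noiseless = generate_ensemble(spec, wells, SurrogateParams(noise_sd=0.0))
    noisy = generate_ensemble(spec, wells, SurrogateParams(noise_sd=0.02, seed=3))
    geometry = build_triene_geometry(spec)
    sigma_ref = SurrogateParams().sigma_ref
    calc = ensemble_site_shifts(noisy, geometry.sites, sigma_ref)
    truth = ensemble_site_shifts(noiseless, geometry.sites, sigma_ref)
    report = fit_linear(calc.shifts, truth.shifts)
    assert report.r2 >= 0.99


class TestMakeRevisionCase:
    def test_noiseless_case_identifiable(self):
        calc, exp, truth = make_revision_case(noise_sd=0.0, seed=1)
        from trienenmr.assignment import SwapSearchSpec, optimize_assignment

        spec = SwapSearchSpec(exchange_groups=tuple(truth.exchange_groups))
        best_map, report, _ = optimize_assignment(calc, exp, spec)
        assert best_map.mapping == truth.mapping
        assert report.r2 == pytest.approx(1.0, abs=1e-12)

    def test_seeded_reproducibility(self):
        a = make_revision_case(noise_sd=0.05, seed=11)
        b = make_revision_case(noise_sd=0.05, seed=11)
        assert a[0].shifts == b[0].shifts
        assert a[1].shifts == b[1].shifts
        assert a[2].mapping == b[2].mapping

    def test_scramble_is_never_identity(self):
        for seed in range(20):
            _, _, truth = make_revision_case(noise_sd=0.0, seed=seed)
            assert truth.n_swaps >= 1

    def test_bad_group_rejected(self):
        with pytest.raises(ValueError):
            make_revision_case(scramble_group=["H1"])
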