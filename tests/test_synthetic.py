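"""Generators: ice lattice geometry, ice rules, gas isotropy, mixture mass
balance and packing, perturbation, isotope labelling, synthetic spectra."""
import math

import numpy as np
import pytest

from hbmap.frames import MOLAR_MASS, minimum_image
from hbmap.spectra import AREA_FACTOR
from hbmap.structure import tetrahedral_q, tetrahedral_q_frame, rdf
from hbmap.synthetic import (
    CompositionSpec,
    LatticeSpec,
    SpectrumSpec,
    build_ice_lattice,
    build_mixture_box,
    build_random_gas,
    mixture_counts,
    perturb_frame,
    substitute_hdo,
    synth_spectrum,
)


class TestIceLattice:
    def test_every_oxygen_has_four_neighbors_at_oo_distance(self, ice_frame):
        ow = ice_frame.coordinates[ice_frame.atom_site == "OW"]
        disp = minimum_image(ow[None, :, :] - ow[:, None, :], ice_frame.box)
        dist = np.linalg.norm(disp, axis=-1)
        np.fill_diagonal(dist, np.inf)
        neighbor_counts = (np.abs(dist - 2.75) < 1e-6).sum(axis=1)
        assert np.all(neighbor_counts == 4)
        assert dist.min() > 2.75 - 1e-6

    def test_perfect_tetrahedral_order(self, ice_frame):
        result = tetrahedral_q_frame(ice_frame)
        assert np.abs(result.q - 1.0).max() < 1e-9

    def test_oh_bonds_point_along_oo_axes(self, ice_frame):
        ow_idx = np.flatnonzero(ice_frame.atom_site == "OW")
        ow = ice_frame.coordinates[ow_idx]
        for mid in ice_frame.molecule_ids()[:20]:
            atoms = ice_frame.atoms_of(mid)
            o = ice_frame.coordinates[atoms[0]]
            for h in atoms[1:]:
                bond = ice_frame.coordinates[h] - o
                target = o + bond / np.linalg.norm(bond) * 2.75
                d = np.linalg.norm(minimum_image(target - ow, ice_frame.box), axis=1)
                assert d.min() < 1e-6  # an oxygen sits on the extended bond axis

    @pytest.mark.parametrize("scheme", ["ordered", "bernal_fowler_random"])
    def test_bernal_fowler_rules(self, scheme):
        frame = build_ice_lattice(
            LatticeSpec(n_cells=(3, 2, 2), oo_distance=2.75, proton_scheme=scheme, seed=4)
        )
        ow_idx = np.flatnonzero(frame.atom_site == "OW")
        ow = frame.coordinates[ow_idx]
        # each molecule has exactly 2 hydrogens by construction; check each
        # O...O link carries exactly one covalent H
        h_idx = np.flatnonzero(np.array([s.startswith("HW") for s in frame.atom_site]))
        link_h = {}
        for h in h_idx:
            o_own = frame.coordinates[frame.atoms_of(frame.molecule_id[h])[0]]
            bond = frame.coordinates[h] - o_own
            target = o_own + bond / np.linalg.norm(bond) * 2.75
            d = np.linalg.norm(minimum_image(target - ow, frame.box), axis=1)
            j = int(np.argmin(d))
            donor = int(frame.molecule_id[h])
            acceptor = int(frame.molecule_id[ow_idx[j]])
            key = (min(donor, acceptor), max(donor, acceptor))
            assert key not in link_h, "two hydrogens on one O...O link"
            link_h[key] = h
        assert len(link_h) == 2 * frame.n_molecules  # 4 links per O, each shared

    def test_random_scheme_seeds_change_protons_not_oxygens(self):
        spec = dict(n_cells=(3, 2, 2), oo_distance=2.75, proton_scheme="bernal_fowler_random")
        f1 = build_ice_lattice(LatticeSpec(**spec, seed=1))
        f2 = build_ice_lattice(LatticeSpec(**spec, seed=2))
        ow = f1.atom_site == "OW"
        assert np.allclose(f1.coordinates[ow], f2.coordinates[ow])
        assert not np.allclose(f1.coordinates, f2.coordinates)

    def test_too_small_supercell_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            build_ice_lattice(LatticeSpec(n_cells=(1, 1, 1), oo_distance=2.75))


class TestRandomGas:
    def test_mean_q_near_zero(self):
        frame = build_random_gas(4096, (40.0, 40.0, 40.0), seed=3)
        result = tetrahedral_q_frame(frame)
        assert abs(result.q.mean()) < 0.02

    def test_perfect_tetrahedron_scores_one(self, topology):
        from hbmap.frames import concatenate_molecules

        # central particle + 4 neighbours at the methane H directions
        dirs = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]]) / math.sqrt(3)
        center = np.full(3, 15.0)
        parts = [(center[None, :], ["X"], "GAS")]
        for d in dirs:
            parts.append(((center + 3.0 * d)[None, :], ["X"], "GAS"))
        frame = concatenate_molecules(parts, np.full(3, 30.0), topology)
        assert tetrahedral_q(frame, 0) == pytest.approx(1.0, abs=1e-12)

    def test_gas_rdf_is_flat(self):
        frame = build_random_gas(2000, (30.0, 30.0, 30.0), seed=5)
        result = rdf(frame, "X", "X", r_max=12.0, dr=0.5)
        beyond_first = result.g[2:]
        sigma = 3.0 / np.sqrt(np.maximum(result.counts[2:], 1))
        assert np.all(np.abs(beyond_first - 1.0) < np.maximum(3 * sigma, 0.12))

    def test_seed_reproducibility(self):
        a = build_random_gas(50, (20, 20, 20), seed=7)
        b = build_random_gas(50, (20, 20, 20), seed=7)
        assert np.array_equal(a.coordinates, b.coordinates)


class TestMixture:
    def test_mass_balance_oracle(self):
        # independent closed-form check: realized mass fractions deviate from
        # the target by less than one molecule's mass share
        spec = CompositionSpec(wt_dmso=33.0, wt_d2o=5.0, n_molecules_total=1000)
        n_dmso, n_hdo, n_h2o = mixture_counts(spec)
        mass = n_dmso * MOLAR_MASS["DMSO"] + n_hdo * MOLAR_MASS["D2O"] + n_h2o * MOLAR_MASS["H2O"]
        realized = n_dmso * MOLAR_MASS["DMSO"] / mass
        assert abs(realized - 0.33) < MOLAR_MASS["DMSO"] / mass
        aq = n_hdo * MOLAR_MASS["D2O"] + n_h2o * MOLAR_MASS["H2O"]
        assert abs(n_hdo * MOLAR_MASS["D2O"] / aq - 0.05) < MOLAR_MASS["D2O"] / aq

    def test_no_dmso_at_zero_weight(self):
        spec = CompositionSpec(wt_dmso=0.0, wt_d2o=5.0, n_molecules_total=100, target_density=1.0)
        frame = build_mixture_box(spec, seed=0)
        assert not np.any(frame.atom_site == "S")

    def test_packing_respects_minimum_distance(self, mixture_frame):
        f = mixture_frame
        disp = minimum_image(f.coordinates[None, :, :] - f.coordinates[:, None, :], f.box)
        dist = np.linalg.norm(disp, axis=-1)
        dist[f.molecule_id[:, None] == f.molecule_id[None, :]] = np.inf
        assert dist.min() >= 1.5

    def test_neutrality(self, mixture_frame):
        assert abs(mixture_frame.charge.sum()) < 1e-10

    def test_packing_failure_raises(self):
        spec = CompositionSpec(wt_dmso=0.0, wt_d2o=0.0, n_molecules_total=60, target_density=8.0)
        with pytest.raises(RuntimeError, match="density"):
            build_mixture_box(spec, seed=0, max_attempts=2000)


class TestPerturb:
    def test_sigma_zero_is_identity(self, ice_frame):
        out = perturb_frame(ice_frame, 0.0, seed=1)
        assert np.array_equal(out.coordinates, ice_frame.coordinates)

    def test_order_parameter_decreases_with_sigma(self, ice_frame):
        means = []
        for sigma in (0.0, 0.05, 0.1, 0.2):
            frame = perturb_frame(ice_frame, sigma, seed=42)
            means.append(tetrahedral_q_frame(frame).q.mean())
        assert means[0] == pytest.approx(1.0, abs=1e-9)
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_seed_contract(self, ice_frame):
        a = perturb_frame(ice_frame, 0.1, seed=3)
        b = perturb_frame(ice_frame, 0.1, seed=3)
        c = perturb_frame(ice_frame, 0.1, seed=4)
        assert np.array_equal(a.coordinates, b.coordinates)
        assert not np.array_equal(a.coordinates, c.coordinates)

    def test_rigid_preserves_internal_geometry(self, ice_frame):
        out = perturb_frame(ice_frame, 0.3, seed=1, rigid=True, rotate_sigma=0.4)
        for mid in ice_frame.molecule_ids()[:10]:
            idx = ice_frame.atoms_of(mid)
            d_in = np.linalg.norm(ice_frame.coordinates[idx[1]] - ice_frame.coordinates[idx[0]])
            d_out = np.linalg.norm(out.coordinates[idx[1]] - out.coordinates[idx[0]])
            assert d_out == pytest.approx(d_in, abs=1e-9)


class TestSubstituteHDO:
    def test_fraction_extremes_and_rounding(self, ice_frame):
        none = substitute_hdo(ice_frame, 0.0, seed=0)
        assert not np.any(none.atom_site == "DW")
        full = substitute_hdo(ice_frame, 1.0, seed=0)
        n_wat = full.n_molecules
        assert int(np.sum(full.atom_site == "DW")) == n_wat
        per_mol = [np.sum(full.atom_site[full.atoms_of(m)] == "DW") for m in full.molecule_ids()[:20]]
        assert all(c == 1 for c in per_mol)

    def test_count_contract(self):
        frame = build_ice_lattice(LatticeSpec(n_cells=(5, 4, 3)))  # 480 waters
        n_waters = frame.n_molecules
        labelled = substitute_hdo(frame, 0.05, seed=2)
        assert int(np.sum(labelled.atom_site == "DW")) == round(0.05 * n_waters)

    def test_charges_untouched(self, ice_frame):
        out = substitute_hdo(ice_frame, 0.5, seed=0)
        assert np.array_equal(out.charge, ice_frame.charge)

    def test_no_water_error(self, topology):
        from hbmap.synthetic import build_random_gas

        gas = build_random_gas(10, (20, 20, 20), seed=0)
        with pytest.raises(ValueError, match="water"):
            substitute_hdo(gas, 0.5, seed=0)


class TestSynthSpectrum:
    def test_single_component_geometry(self):
        spec = SpectrumSpec(components=[(2450.0, 80.0, 1.3)], grid=(2300, 2600, 0.5))
        s = synth_spectrum(spec)
        peak_idx = np.argmax(s.absorbance)
        assert s.wavenumber[peak_idx] == pytest.approx(2450.0, abs=0.5)
        assert s.absorbance.max() == pytest.approx(1.3, abs=1e-12)
        for side in (2450.0 - 40.0, 2450.0 + 40.0):
            value = s.absorbance[np.argmin(np.abs(s.wavenumber - side))]
            assert value == pytest.approx(0.65, abs=1e-12)

    def test_integral_matches_analytic_areas(self):
        comps = [(2400.0, 25.0, 1.0), (2350.0, 30.0, 0.4), (2450.0, 28.0, 0.5), (2470.0, 120.0, 0.6)]
        spec = SpectrumSpec(components=comps, grid=(2000, 2900, 0.25))
        s = synth_spectrum(spec)
        numeric = np.trapezoid(s.absorbance, s.wavenumber)
        analytic = sum(a * w * AREA_FACTOR for _, w, a in comps)
        assert numeric == pytest.approx(analytic, rel=1e-6)

    def test_noise_reproducible_under_seed(self):
        spec = SpectrumSpec(components=[(2450.0, 60.0, 1.0)], noise_sd=0.01, seed=5)
        assert np.array_equal(synth_spectrum(spec).absorbance, synth_spectrum(spec).absorbance)
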