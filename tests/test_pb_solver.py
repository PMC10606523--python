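import math

import numpy as np
import pytest

from pkagrid import constants
from pkagrid import synthetic_data as synth
from pkagrid.dielectric_model import GridSpec, build_eps_map, grid_from_structure, uniform_map
from pkagrid.pb_solver import (
    SolverError,
    SolverSettings,
    background_energy,
    coulomb_energy,
    dielectric_response_energy,
    interaction_energy,
    potential_at,
    solve,
)
from pkagrid.structure_io import assign_parse, find_titratable_sites

NO_SALT = SolverSettings(ionic_strength=0.0)


def water_box(eps=81.0, ionic=0.0, spacing=0.8, half=16.0):
    n = int(round(2 * half / spacing)) + 1
    grid = GridSpec(origin=(-half, -half, -half), spacing=spacing, dims=(n, n, n))
    return uniform_map(grid, eps, ionic)


class TestPotential:
    def test_coulomb_limit_far_from_charge(self):
        dmap = water_box()
        pg = solve(dmap, [(np.zeros(3), 1.0)], NO_SALT)
        phi = potential_at(pg, np.array([[5.0, 0.0, 0.0]]))[0]
        exact = constants.COULOMB_KCAL_A / (81.0 * 5.0) / constants.kt_kcal()
        assert phi == pytest.approx(exact, rel=0.02)
        assert phi == pytest.approx(1.38, rel=0.03)

    def test_zero_source_gives_zero_potential(self):
        dmap = water_box()
        pg = solve(dmap, [(np.zeros(3), 0.0)], NO_SALT)
        assert np.allclose(pg.phi, 0.0)

    def test_debye_screened_form(self):
        dmap = water_box(ionic=0.2)
        settings = SolverSettings(ionic_strength=0.2)
        pg = solve(dmap, [(np.zeros(3), 1.0)], settings)
        kappa = math.sqrt(constants.eps_kappa_sq(0.2) / 81.0)
        assert 1.0 / kappa == pytest.approx(6.9, abs=0.1)
        r = 5.0
        phi = potential_at(pg, np.array([[r, 0.0, 0.0]]))[0]
        exact = constants.COULOMB_KCAL_A / (81.0 * r) * math.exp(-kappa * r) / constants.kt_kcal()
        assert phi == pytest.approx(exact, rel=0.05)

    def test_nonconvergence_carries_residual_history(self):
        dmap = water_box(spacing=1.0, half=10.0)
        with pytest.raises(SolverError) as err:
            solve(dmap, [(np.zeros(3), 1.0)], SolverSettings(ionic_strength=0.0, max_iterations=2))
        assert len(err.value.residual_history) > 0


class TestResponseEnergy:
    def born_maps(self, a=2.0, eps_out=(81.0, 4.0), spacing=1.0):
        st, analytic = synth.make_born_sphere(a=a, eps_from=eps_out[0], eps_to=eps_out[1])
        grid = grid_from_structure(st, spacing=spacing, margin=13.0)
        maps = [
            build_eps_map(st, grid, eps_solvent=e, ionic_strength=0.0) for e in eps_out
        ]
        return st, grid, maps, analytic

    def test_born_transfer_matches_analytic(self):
        _, _, (m_from, m_to), analytic = self.born_maps()
        dd = dielectric_response_energy(
            m_to, m_from, [(np.zeros(3), 1.0)], NO_SALT,
            focus_center=np.zeros(3), focus_halfwidth=6.0, fine_spacing=0.25,
        )
        assert analytic == pytest.approx(19.7, abs=0.1)
        assert dd == pytest.approx(analytic, rel=0.03)

    def test_identical_environments_cancel_exactly(self):
        _, _, (m_from, _), _ = self.born_maps()
        dd = dielectric_response_energy(m_from, m_from, [(np.zeros(3), 1.0)], NO_SALT)
        assert dd == pytest.approx(0.0, abs=1e-9)

    def test_quadratic_charge_scaling(self):
        _, _, (m_from, m_to), _ = self.born_maps()
        d1 = dielectric_response_energy(m_to, m_from, [(np.zeros(3), 1.0)], NO_SALT)
        d2 = dielectric_response_energy(m_to, m_from, [(np.zeros(3), 2.0)], NO_SALT)
        assert d2 == pytest.approx(4.0 * d1, rel=1e-6)

    def test_grid_refinement_reduces_born_error(self):
        errors = []
        for spacing in (1.0, 0.5):
            _, _, (m_from, m_to), analytic = self.born_maps(spacing=spacing)
            dd = dielectric_response_energy(m_to, m_from, [(np.zeros(3), 1.0)], NO_SALT)
            errors.append(abs(dd - analytic) / analytic)
        assert errors[1] < errors[0]

    def test_offgrid_translation_cancels_self_energy(self):
        # moving the whole system by a non-integer number of cells changes
        # the response energy by < 0.5%
        vals = []
        for shift in (0.0, 0.37):
            center = np.full(3, shift)
            grid = GridSpec(origin=(-15, -15, -15), spacing=1.0, dims=(31, 31, 31))
            st_s = synth.make_born_sphere()[0]
            st_s.atoms[0].position = center
            m81 = build_eps_map(st_s, grid, eps_solvent=81.0, ionic_strength=0.0)
            m4 = build_eps_map(st_s, grid, eps_solvent=4.0, ionic_strength=0.0)
            vals.append(
                dielectric_response_energy(
                    m4, m81, [(center, 1.0)], NO_SALT,
                    focus_center=center, focus_halfwidth=6.0, fine_spacing=0.25,
                )
            )
        assert abs(vals[1] - vals[0]) / abs(vals[0]) < 0.005

    def test_mismatched_grids_rejected(self):
        _, _, (m_from, m_to), _ = self.born_maps()
        other = water_box(spacing=1.0, half=10.0)
        with pytest.raises(SolverError, match="grid"):
            dielectric_response_energy(other, m_from, [(np.zeros(3), 1.0)], NO_SALT)


class TestInteractionEnergy:
    def test_coulomb_pair_in_uniform_medium(self):
        st, analytic = synth.make_charge_pair(1.0, 1.0, 6.0, 20.0)
        dmap = water_box(eps=20.0)
        w = interaction_energy(
            dmap, [(st.atoms[0].position, 1.0)], [(st.atoms[1].position, 1.0)], NO_SALT
        )
        assert analytic == pytest.approx(2.77, abs=0.01)
        assert w == pytest.approx(analytic, rel=0.02)

    def test_zero_probe_charge(self):
        dmap = water_box(eps=20.0)
        w = interaction_energy(dmap, [(np.zeros(3), 1.0)], [(np.array([6.0, 0, 0]), 0.0)], NO_SALT)
        assert w == 0.0

    def test_reciprocity(self):
        dmap = water_box(eps=20.0)
        a = [(np.array([-3.0, 0.4, 0.0]), 1.0)]
        b = [(np.array([3.0, -0.2, 0.6]), -0.7)]
        wab = interaction_energy(dmap, a, b, NO_SALT)
        wba = interaction_energy(dmap, b, a, NO_SALT)
        assert wab == pytest.approx(wba, rel=0.01)

    def test_overlapping_sites_rejected(self):
        dmap = water_box(eps=20.0)
        with pytest.raises(SolverError, match="overlap"):
            interaction_energy(dmap, [(np.zeros(3), 1.0)], [(np.zeros(3), 1.0)], NO_SALT)

    def test_salt_screening_is_monotone(self):
        a = [(np.array([-5.0, 0.0, 0.0]), 1.0)]
        b = [(np.array([5.0, 0.0, 0.0]), 1.0)]
        energies = []
        for ionic in (0.0, 0.05, 0.2):
            dmap = water_box(eps=81.0, ionic=ionic)
            energies.append(
                interaction_energy(dmap, a, b, SolverSettings(ionic_strength=ionic))
            )
        assert energies[0] > energies[1] > energies[2] > 0


class TestBackgroundEnergy:
    def test_point_background_matches_coulomb(self, helix_sites):
        dmap = water_box(eps=10.0)
        site = helix_sites[0]
        # collapse the site to a single +1 delta charge at a known point
        site = type(site)(
            site_id="X", residue_type="GLU", acid_or_base="acid", model_pka=4.4,
            protonated_charges={"CD": 1.0}, deprotonated_charges={"CD": 0.0},
            chain_id="A", residue_number=1,
            atom_positions={"CD": np.zeros(3)}, atom_indices={"CD": 0},
        )
        bg = [(np.array([4.0, 0.0, 0.0]), -0.5)]
        dg = background_energy(dmap, site, bg, NO_SALT)
        assert dg == pytest.approx(-constants.COULOMB_KCAL_A * 0.5 / (10 * 4), rel=0.05)
        assert dg == pytest.approx(-4.15, abs=0.25)

    def test_helix_backbone_field_matches_coulomb_sum(self):
        # toy helix in a uniform medium: FD background energy vs brute-force
        # Coulomb sum over the backbone dipole charges
        st = assign_parse(synth.make_helix_in_slab([("GLU", 8)], n_residues=8))
        sites = find_titratable_sites(st)
        site = sites[0]
        eps0 = 20.0
        dmap = water_box(eps=eps0, spacing=0.6, half=18.0)
        background = [
            (a.position, a.partial_charge)
            for a in st.atoms
            if abs(a.partial_charge) > 1e-12 and a.name in ("C", "O")
        ]
        dg = background_energy(dmap, site, background, NO_SALT)
        oracle = coulomb_energy(site.charge_set("delta"), background, eps0)
        assert dg == pytest.approx(oracle, rel=0.05)

    def test_background_containing_site_atoms_rejected(self, helix_sites):
        dmap = water_box(eps=10.0)
        site = helix_sites[0]
        bg = [(site.atom_positions["CD"], 0.3)]
        with pytest.raises(SolverError, match="titratable"):
            background_energy(dmap, site, bg, NO_SALT)

    def test_empty_background_is_zero(self, helix_sites):
        dmap = water_box(eps=10.0)
        assert background_energy(dmap, helix_sites[0], [], NO_SALT) == 0.0
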