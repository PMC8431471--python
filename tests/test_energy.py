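import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ertraj.energy import (AtomParameters, COULOMB_CONSTANT,
                           EnergyComponents, EvaluatorOptions,
                           binding_free_energy, sasa, single_point_energy,
                           sum_components, trajectory_energy_profile)
from ertraj.synthetic import (SyntheticSpec, default_parameters,
                              generate_energy_toy_system,
                              generate_receptor_ligand_trajectory)

NO_SASA = EvaluatorOptions(surface_tension=0.0)


def naive_components(coords, params, options=NO_SASA):
    """Independent O(n²) double-loop re-implementation of the pairwise
    terms (Coulomb, LJ, Still GB)."""
    n = len(coords)
    coulomb = vdw = 0.0
    tau = 1.0 / options.dielectric_in - 1.0 / options.dielectric_out
    gb_sum = 0.0
    for i in range(n):
        for j in range(n):
            a_i, a_j = params.born_radius[i], params.born_radius[j]
            if i == j:
                gb_sum += params.charge[i] ** 2 / a_i
                continue
            r = math.dist(coords[i], coords[j])
            f = math.sqrt(r * r + a_i * a_j
                          * math.exp(-r * r / (4 * a_i * a_j)))
            gb_sum += params.charge[i] * params.charge[j] / f
            if i < j:
                coulomb += (COULOMB_CONSTANT * params.charge[i]
                            * params.charge[j]
                            / (options.dielectric_in * r))
                s = 0.5 * (params.sigma[i] + params.sigma[j])
                e = math.sqrt(params.epsilon[i] * params.epsilon[j])
                vdw += 4 * e * ((s / r) ** 12 - (s / r) ** 6)
    return coulomb, vdw, -0.5 * COULOMB_CONSTANT * tau * gb_sum


class TestSumAndCycle:
    def test_component_sum_examples(self):
        assert sum_components(EnergyComponents()) == 0.0
        assert sum_components(EnergyComponents(1, 1, 1, 1, 1, 1, 1)) == 7.0

    def test_sum_matches_reverse_order_re_summation(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(scale=50, size=7)
        c = EnergyComponents(*vals)
        assert sum_components(c) == pytest.approx(sum(reversed(vals.tolist())),
                                                  abs=1e-9)

    @pytest.mark.parametrize("e_cplx,e_rec,e_lig,expected", [
        (-9402.71, -9360.34, 1.73, -44.10),
        (-9342.13, -9332.01, 32.12, -42.24),
    ])
    def test_cycle_reproduces_reference_rows_exactly(self, e_cplx, e_rec,
                                                     e_lig, expected):
        result = binding_free_energy(e_cplx, e_rec, e_lig)
        assert result.delta_g_bind == pytest.approx(expected, abs=5e-3)

    def test_zero_ligand_energy_and_identical_species_gives_zero(self):
        assert binding_free_energy(-123.4, -123.4, 0.0).delta_g_bind == 0.0

    @given(st.tuples(*[st.floats(-1e4, 1e4) for _ in range(3)]),
           st.floats(-100, 100))
    @settings(max_examples=200, deadline=None)
    def test_cycle_is_linear_with_signs_plus_minus_minus(self, triple, c):
        e1, e2, e3 = triple
        base = binding_free_energy(e1, e2, e3).delta_g_bind
        shifted = binding_free_energy(e1 + c, e2, e3).delta_g_bind
        assert shifted == pytest.approx(base + c, abs=1e-6)
        shifted = binding_free_energy(e1, e2 + c, e3).delta_g_bind
        assert shifted == pytest.approx(base - c, abs=1e-6)

    def test_non_finite_inputs_rejected(self):
        with pytest.raises(ValueError):
            binding_free_energy(np.nan, 0.0, 0.0)


class TestClosedForms:
    def test_born_ion_solvation(self):
        q, a = 1.0, 2.0
        params = AtomParameters([q], [3.0], [0.1], [a], [False])
        c = single_point_energy(np.zeros((1, 3)), params, NO_SASA)
        expected = -166.0318 * (1 - 1 / 78.5) * q ** 2 / a
        assert c.solv_gb == pytest.approx(expected, rel=1e-6)

    def test_lj_minimum_is_minus_epsilon(self):
        sigma, eps = 3.4, 0.21
        r = 2 ** (1 / 6) * sigma
        params = AtomParameters([0, 0], [sigma] * 2, [eps] * 2, [1.5] * 2,
                                [False] * 2)
        c = single_point_energy(np.array([[0, 0, 0], [r, 0, 0.0]]), params,
                                NO_SASA)
        assert c.vdw == pytest.approx(-eps, rel=1e-12)
        assert c.coulomb == 0.0
        assert c.solv_gb == 0.0

    def test_electrostatics_scale_quadratically_with_charge(self):
        sys_ = generate_energy_toy_system(seed=4)
        params = sys_.complex_params
        c1 = single_point_energy(sys_.complex_coords, params, NO_SASA)
        params2 = AtomParameters(params.charge * 2.0, params.sigma,
                                 params.epsilon, params.born_radius,
                                 params.hydrophobic)
        c2 = single_point_energy(sys_.complex_coords, params2, NO_SASA)
        assert c2.coulomb == pytest.approx(4 * c1.coulomb, rel=1e-10)
        assert c2.solv_gb == pytest.approx(4 * c1.solv_gb, rel=1e-10)
        assert c2.vdw == pytest.approx(c1.vdw, rel=1e-12)

    def test_agrees_with_naive_double_loop(self):
        sys_ = generate_energy_toy_system(seed=6, n_receptor=38, n_ligand=10)
        coords = sys_.complex_coords
        params = sys_.complex_params
        c = single_point_energy(coords, params, NO_SASA)
        coulomb, vdw, gb = naive_components(coords, params)
        assert c.coulomb == pytest.approx(coulomb, abs=1e-8)
        assert c.vdw == pytest.approx(vdw, abs=1e-8)
        assert c.solv_gb == pytest.approx(gb, abs=1e-8)

    def test_missing_parameters_error_names_the_mismatch(self):
        params = AtomParameters([0.0], [3.0], [0.1], [1.5], [True])
        with pytest.raises(ValueError, match="1 atoms"):
            single_point_energy(np.zeros((3, 3)), params)


class TestSASA:
    def test_isolated_sphere_area_closed_form(self):
        areas = sasa(np.zeros((1, 3)), np.array([1.7]), probe_radius=1.4)
        assert areas[0] == pytest.approx(4 * np.pi * (1.7 + 1.4) ** 2,
                                         rel=1e-9)

    def test_distant_atoms_are_additive(self):
        coords = np.array([[0, 0, 0], [100.0, 0, 0]])
        radii = np.array([1.7, 1.5])
        areas = sasa(coords, radii)
        assert areas[0] == pytest.approx(4 * np.pi * 3.1 ** 2, rel=1e-9)
        assert areas[1] == pytest.approx(4 * np.pi * 2.9 ** 2, rel=1e-9)

    def test_buried_atom_loses_area(self):
        coords = np.array([[0, 0, 0], [1.0, 0, 0]])
        radii = np.array([1.7, 1.7])
        areas = sasa(coords, radii)
        assert areas.sum() < 2 * 4 * np.pi * 3.1 ** 2


@pytest.fixture(scope="module")
def contact_run():
    spec = SyntheticSpec(n_frames=60, fraction_displaced=0.3, seed=13)
    return generate_receptor_ligand_trajectory(spec)


class TestTrajectoryProfile:

    def test_duplicate_representatives_give_identical_results(
            self, contact_run):
        traj, _ = contact_run
        params = default_parameters(traj)
        out = trajectory_energy_profile(traj, params, [7, 7])
        assert out[0].binding == out[1].binding

    def test_noninteracting_limit_is_zero(self):
        # ligand 150 Å away, all charges zero, no surface term
        rng = np.random.default_rng(2)
        rec = rng.uniform(0, 10, (20, 3))
        lig = rng.uniform(0, 5, (5, 3)) + 150.0
        from ertraj.core import Atom
        from conftest import make_trajectory
        atoms = [Atom(i + 1, "CA", "C", "ALA", i + 1, "A")
                 for i in range(20)]
        atoms += [Atom(21 + i, f"C{i+1}", "C", "LIG", 900, "A",
                       is_ligand=True) for i in range(5)]
        traj = make_trajectory(atoms, [np.vstack([rec, lig])])
        params = AtomParameters(np.zeros(25), np.full(25, 3.4),
                                np.full(25, 0.1), np.full(25, 1.7),
                                np.zeros(25, bool))
        out = trajectory_energy_profile(traj, params, [1], NO_SASA)
        assert out[0].binding.delta_g_bind == pytest.approx(0.0, abs=1e-6)

    def test_bound_pose_has_lower_binding_energy_than_unbound(
            self, contact_run):
        """Frames where the planted contacts are formed must score a more
        favorable ΔG_bind than frames where every contact is broken."""
        from ertraj.interactions import detect_hbonds, detect_hydrophobic
        traj, _ = contact_run
        params = default_parameters(traj)
        n_contacts = []
        for f in traj.frames:
            n = len(detect_hbonds(f, traj)) + len(
                {r for _, r in detect_hydrophobic(f, traj)})
            n_contacts.append(n)
        n_contacts = np.array(n_contacts)
        bound = int(np.argmax(n_contacts)) + 1
        unbound = int(np.argmin(n_contacts)) + 1
        assert n_contacts.max() > n_contacts.min()
        out = trajectory_energy_profile(traj, params, [bound, unbound])
        assert out[0].binding.delta_g_bind < out[1].binding.delta_g_bind

    def test_empty_representatives_rejected(self, contact_run):
        traj, _ = contact_run
        with pytest.raises(ValueError, match="non-empty"):
            trajectory_energy_profile(traj, default_parameters(traj), [])
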