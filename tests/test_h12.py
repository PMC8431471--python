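import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from ertraj.core import Atom, Frame, ResidueSelection, Trajectory
from ertraj.h12 import (GAS_CONSTANT_KCAL, activation_energy, classify_forms,
                        h12_distance, lbp_centroid, relative_distance_series)
from ertraj.synthetic import (SyntheticSpec,
                              generate_receptor_ligand_trajectory,
                              h12_selection, lbp_selection)

from conftest import make_trajectory


def ca_trajectory(positions_per_frame, start_res=1):
    """CA-only trajectory from per-frame lists of CA positions."""
    n_res = len(positions_per_frame[0])
    atoms = [Atom(i + 1, "CA", "C", "ALA", start_res + i, "A")
             for i in range(n_res)]
    return make_trajectory(atoms, [np.asarray(p, float)
                                   for p in positions_per_frame])


class TestCentroidAndDistance:
    def test_centroid_of_two_atoms_is_midpoint(self):
        traj = ca_trajectory([[[0, 0, 0], [2, 0, 0]]])
        sel = ResidueSelection("lbp", [("A", 1), ("A", 2)])
        np.testing.assert_allclose(
            lbp_centroid(traj.frames[0], traj, sel), [1, 0, 0])

    def test_centroid_of_single_atom_is_that_atom(self):
        traj = ca_trajectory([[[3, 4, 5], [9, 9, 9]]])
        sel = ResidueSelection("lbp", [("A", 1)])
        np.testing.assert_allclose(
            lbp_centroid(traj.frames[0], traj, sel), [3, 4, 5])

    def test_centroid_matches_independent_summation(self, default_run):
        traj, _ = default_run
        frame = traj.frames[10]
        sel = lbp_selection()
        got = lbp_centroid(frame, traj, sel)
        total = np.zeros(3)
        count = 0
        for i, atom in enumerate(traj.topology):
            if atom.name == "CA" and (atom.chain_id,
                                      atom.residue_number) in set(sel.members):
                total += frame.coordinates[i]
                count += 1
        np.testing.assert_allclose(got, total / count, atol=1e-12)

    def test_max_rule_over_equidistant_residues(self):
        ring = [[5 * np.cos(a), 5 * np.sin(a), 0]
                for a in np.linspace(0, 2 * np.pi, 8, endpoint=False)]
        traj = ca_trajectory([ring])
        sel = ResidueSelection("h12", [("A", r) for r in range(1, 9)])
        assert h12_distance(traj.frames[0], traj, sel,
                            np.zeros(3)) == pytest.approx(5.0)

    def test_max_rule_picks_the_farthest_residue(self):
        pts = [[5, 0, 0], [0, 5, 0], [0, 0, 9]]
        traj = ca_trajectory([pts])
        sel = ResidueSelection("h12", [("A", r) for r in (1, 2, 3)])
        assert h12_distance(traj.frames[0], traj, sel,
                            np.zeros(3)) == pytest.approx(9.0)

    def test_translating_h12_along_its_axis_adds_exactly(self, default_run):
        traj, _ = default_run
        frame = traj.frames[0]
        lbp_idx_centroid = lbp_centroid(frame, traj, lbp_selection())
        base = h12_distance(frame, traj, h12_selection(), lbp_idx_centroid)
        # shift every H12 atom +4 Å along the direction of its farthest CA
        from ertraj.core import resolve_selection
        idx = resolve_selection(traj, h12_selection())
        d = np.linalg.norm(frame.coordinates[idx] - lbp_idx_centroid, axis=1)
        far = idx[np.argmax(d)]
        u = frame.coordinates[far] - lbp_idx_centroid
        u /= np.linalg.norm(u)
        moved = frame.coordinates.copy()
        moved[idx] += 4.0 * u
        shifted = Frame(moved, frame.time_ps, frame.index)
        assert h12_distance(shifted, traj, h12_selection(),
                            lbp_idx_centroid) == pytest.approx(base + 4.0,
                                                               abs=1e-6)

    def test_rigid_motion_of_whole_frame_preserves_distance(self,
                                                            default_run):
        traj, _ = default_run
        frame = traj.frames[5]
        rot = Rotation.from_euler("zyx", [13, 27, 41],
                                  degrees=True).as_matrix()
        moved = Frame(frame.coordinates @ rot.T + np.array([3.0, -8.0, 2.0]),
                      frame.time_ps, frame.index)
        for f in (frame, moved):
            c = lbp_centroid(f, traj, lbp_selection())
            if f is frame:
                ref = h12_distance(f, traj, h12_selection(), c)
            else:
                assert h12_distance(f, traj, h12_selection(), c) == \
                    pytest.approx(ref, abs=1e-9)


class TestRelativeSeries:
    def test_static_trajectory_gives_all_zero(self):
        pts = np.random.default_rng(0).normal(size=(20, 3)) * 5
        traj = ca_trajectory([pts] * 5)
        prof = relative_distance_series(
            traj,
            ResidueSelection("lbp", [("A", r) for r in range(1, 11)]),
            ResidueSelection("h12", [("A", r) for r in range(11, 21)]))
        np.testing.assert_allclose(prof.data.relative_distance_A, 0.0,
                                   atol=1e-12)
        assert prof.data.relative_distance_A.iloc[0] == 0.0

    def test_planted_linear_ramp_recovered(self):
        pocket = np.random.default_rng(1).normal(size=(10, 3))
        pocket -= pocket.mean(0)  # centroid exactly at the origin
        base = np.vstack([pocket,
                          np.array([[0, 0, 20 + i] for i in range(5)])])
        frames = []
        for k in range(50):
            xyz = base.copy()
            xyz[10:, 2] += 0.01 * k  # move the distal segment outward
            frames.append(xyz)
        traj = ca_trajectory(frames)
        prof = relative_distance_series(
            traj,
            ResidueSelection("lbp", [("A", r) for r in range(1, 11)]),
            ResidueSelection("h12", [("A", r) for r in range(11, 16)]))
        ramp = prof.data.relative_distance_A.to_numpy()
        expected = 0.01 * np.arange(50)
        np.testing.assert_allclose(ramp, expected, atol=1e-6)


class TestClassification:
    @staticmethod
    def _profile_from(rel):
        import pandas as pd
        from ertraj.h12 import H12Profile
        data = pd.DataFrame({
            "frame": np.arange(1, len(rel) + 1),
            "time_ps": np.arange(len(rel)) * 4.8,
            "h12_distance_A": 30.0 + np.asarray(rel),
            "relative_distance_A": rel,
        })
        return H12Profile(data=data)

    def test_all_positive_from_active_start_become_inactive(self):
        prof = classify_forms(self._profile_from([0.0, 2.0, 2.0, 2.0]),
                              "active")
        # frame 1 (relative 0) stays with the initial form
        assert prof.n_inactive == 3
        assert prof.n_active == 1

    def test_boundary_frames_inherit_initial_form(self):
        prof = classify_forms(self._profile_from([0.0, 0.0]), "active", 0.0)
        assert prof.n_active == 2
        prof = classify_forms(self._profile_from([0.0, 0.0]), "inactive")
        assert prof.n_inactive == 2

    def test_threshold_widens_the_boundary_band(self):
        prof = classify_forms(self._profile_from([0.0, 0.4, -0.4, 1.0]),
                              "active", threshold_A=0.5)
        assert prof.n_inactive == 1  # only the +1.0 frame

    def test_planted_fraction_recovered_within_binomial_error(self):
        spec = SyntheticSpec(n_frames=1000, fraction_displaced=0.3, seed=21)
        traj, truth = generate_receptor_ligand_trajectory(spec)
        prof = classify_forms(
            relative_distance_series(traj, lbp_selection(), h12_selection()),
            "active")
        frac = prof.n_inactive / traj.n_frames
        assert abs(frac - 0.3) <= 3 * np.sqrt(0.3 * 0.7 / 1000)
        # classification reproduces the planted flags frame by frame
        # (frame 1 is the reference and counted with the initial form)
        labels = prof.data.label.to_numpy()
        np.testing.assert_array_equal(labels[1:] == "inactive",
                                      truth.displaced[1:])


class TestActivationEnergy:
    def test_equal_populations_give_zero(self):
        assert activation_energy(123, 123, 310.0) == 0.0

    def test_ratio_e_at_310K(self):
        n = 100000
        value = activation_energy(int(n * np.e), n, 310.0)
        assert value == pytest.approx(-0.61603, abs=1e-4)

    @given(st.integers(1, 10 ** 6), st.integers(1, 10 ** 6),
           st.floats(1.0, 500.0))
    @settings(max_examples=200, deadline=None)
    def test_antisymmetric_under_population_swap(self, a, b, t):
        assert activation_energy(a, b, t) == pytest.approx(
            -activation_energy(b, a, t), abs=1e-12)

    def test_zero_population_error_mentions_pseudo_count(self):
        with pytest.raises(ValueError, match="pseudo-count"):
            activation_energy(0, 5)

    def test_gas_constant_value(self):
        assert GAS_CONSTANT_KCAL == pytest.approx(1.9872e-3)
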