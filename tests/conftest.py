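"""Shared fixtures: hand-built miniature topologies and session-scoped
synthetic trajectories."""

from __future__ import annotations

import numpy as np
import pytest

from ertraj.core import Atom, Frame, Trajectory
from ertraj.synthetic import (SyntheticSpec,
                              generate_receptor_ligand_trajectory)


def make_trajectory(atoms, frame_coords, interval=4.8):
    frames = [
        Frame(coordinates=np.asarray(c, dtype=float), time_ps=i * interval,
              index=i + 1)
        for i, c in enumerate(frame_coords)
    ]
    return Trajectory(topology=list(atoms), frames=frames,
                      frame_interval_ps=interval)


@pytest.fixture
def glycine_trajectory():
    """One glycine (with hydrogens) plus a ligand atom — for atom-mode
    resolution tests."""
    atoms = [
        Atom(1, "N", "N", "GLY", 10, "A"),
        Atom(2, "CA", "C", "GLY", 10, "A"),
        Atom(3, "C", "C", "GLY", 10, "A"),
        Atom(4, "O", "O", "GLY", 10, "A"),
        Atom(5, "HA2", "H", "GLY", 10, "A"),
        Atom(6, "HA3", "H", "GLY", 10, "A"),
        Atom(7, "C1", "C", "LIG", 90, "A", is_ligand=True),
    ]
    coords = np.arange(21, dtype=float).reshape(7, 3)
    return make_trajectory(atoms, [coords])


@pytest.fixture
def pocket_trajectory():
    """A CA-only topology carrying the canonical 17 ERα pocket residue
    numbers (Met343 ... Leu525) on chain A."""
    numbers = [343, 346, 347, 349, 350, 351, 353, 384, 387, 391, 394, 404,
               421, 428, 521, 524, 525]
    names = ["MET", "LEU", "THR", "LEU", "ALA", "ASP", "GLU", "LEU", "LEU",
             "LEU", "ARG", "PHE", "MET", "LEU", "GLY", "HIS", "LEU"]
    atoms = [
        Atom(i + 1, "CA", "C", nm, num, "A")
        for i, (nm, num) in enumerate(zip(names, numbers))
    ]
    rng = np.random.default_rng(0)
    coords = rng.uniform(-5, 5, size=(17, 3))
    return make_trajectory(atoms, [coords])


@pytest.fixture(scope="session")
def basin_run():
    """600-frame, 3-basin trajectory with the H12 switch quiet — the
    canonical clustering-recovery condition."""
    spec = SyntheticSpec(n_frames=600, n_basins=3, basin_displacement_A=8.0,
                         noise_sigma_A=0.5, fraction_displaced=0.0, seed=42)
    return generate_receptor_ligand_trajectory(spec)


@pytest.fixture(scope="session")
def default_run():
    """Busy trajectory: 3 basins, a 30% displaced H12 switch, contacts."""
    spec = SyntheticSpec(n_frames=600, fraction_displaced=0.3, seed=7)
    return generate_receptor_ligand_trajectory(spec)
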