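"""Synthetic receptor–ligand trajectories with known ground truth.

The generator emulates the statistical structure of a nuclear-receptor
ligand-binding-domain simulation without any force-field dynamics:

* a small ideal-helix receptor scaffold (64 residues, numbered 486–549 so
  that the helix-12 segment carries the canonical ERα numbering 535–549),
* multi-basin conformational exchange: a mobile loop (residues 523–534)
  sits at one of ``n_basins`` planted offsets, giving block structure in
  the all-vs-all RMSD matrix,
* a two-state helix-12 switch: frames flagged "displaced" have H12
  translated *away* from the ligand-binding-pocket centroid, the others
  slightly *toward* it, so the sign of the relative H12 distance encodes
  the planted state,
* ligand–residue contacts toggled per frame by independent Bernoulli
  draws at planted persistence fractions (side-chain marker atoms placed
  inside/outside the contact cutoff; these markers and the rigid ligand
  carry no noise so detection is exact and recovery error is purely
  binomial).

Everything is deterministic given ``seed``.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import Atom, AtomMode, Frame, ResidueSelection, Trajectory
from .energy import AtomParameters

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "generate_receptor_ligand_trajectory",
    "generate_energy_toy_system",
    "ToyEnergySystem",
    "default_parameters",
    "LBP_RESIDUE_NUMBERS",
    "H12_RANGE",
    "lbp_selection",
    "h12_selection",
    "fit_selection",
]

# scaffold layout (chain A throughout)
_FIRST_RES = 486
_N_RES = 64
H12_RANGE = (535, 549)
_LOOP_RANGE = (523, 534)
#: 17 pocket residues used for the LBP centroid, mirroring the size of the
#: ERα pocket-residue set
LBP_RESIDUE_NUMBERS = tuple(range(490, 523, 2))

_HELIX_RADIUS = 2.3  # Å
_HELIX_RISE = 1.5  # Å per residue
_HELIX_TWIST = math.radians(100.0)

_DEFAULT_CONTACTS = {
    "LEU492": 0.65,
    "PHE500": 0.45,
    "SER510": 0.70,
    "ALA516": 0.15,
}
_DEFAULT_HBOND_RESIDUES = frozenset({"SER510"})

_LABEL_RE = re.compile(r"^([A-Z]{3})(\d+)$")


def lbp_selection(atom_mode: AtomMode = AtomMode.CA_ONLY) -> ResidueSelection:
    """The generator's 17-residue pocket-centroid selection."""
    return ResidueSelection(
        "LBP", [("A", n) for n in LBP_RESIDUE_NUMBERS], atom_mode
    )


def h12_selection(atom_mode: AtomMode = AtomMode.CA_ONLY) -> ResidueSelection:
    """Helix-12 segment, residues 535–549."""
    return ResidueSelection.from_range("H12", "A", *H12_RANGE,
                                       atom_mode=atom_mode)


def fit_selection(atom_mode: AtomMode = AtomMode.CA_ONLY) -> ResidueSelection:
    """Whole-receptor selection used for superposition by default."""
    return ResidueSelection.from_range(
        "receptor", "A", _FIRST_RES, _FIRST_RES + _N_RES - 1,
        atom_mode=atom_mode,
    )


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic trajectory.

    ``basin_weights`` defaults to uniform; ``fraction_displaced`` is the
    planted probability that a frame has H12 in the outward (inactive-like)
    position; ``contact_persistence`` maps residue labels such as
    ``"LEU492"`` to planted per-frame contact probabilities.
    """

    n_frames: int = 600
    n_basins: int = 3
    basin_weights: tuple[float, ...] | None = None
    basin_displacement_A: float = 8.0
    noise_sigma_A: float = 0.5
    fraction_displaced: float = 0.0
    h12_displacement_A: float = 4.0
    contact_persistence: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_CONTACTS)
    )
    hbond_residues: frozenset[str] = _DEFAULT_HBOND_RESIDUES
    seed: int = 0
    frame_interval_ps: float = 4.8

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.n_basins < 1:
            raise ValueError("n_basins must be >= 1")
        if not 0.0 <= self.fraction_displaced <= 1.0:
            raise ValueError("fraction_displaced must lie in [0, 1]")
        if self.basin_weights is None:
            self.basin_weights = tuple(
                1.0 / self.n_basins for _ in range(self.n_basins)
            )
        self.basin_weights = tuple(float(w) for w in self.basin_weights)
        if len(self.basin_weights) != self.n_basins:
            raise ValueError("basin_weights length must equal n_basins")
        if any(w < 0 for w in self.basin_weights) or not math.isclose(
            sum(self.basin_weights), 1.0, abs_tol=1e-8
        ):
            raise ValueError("basin_weights must be non-negative and sum to 1")
        last = _FIRST_RES + _N_RES - 1
        for label, p in self.contact_persistence.items():
            m = _LABEL_RE.match(label)
            if not m:
                raise ValueError(f"contact label {label!r} not NAME###")
            num = int(m.group(2))
            if not _FIRST_RES <= num <= last \
                    or H12_RANGE[0] <= num <= H12_RANGE[1]:
                raise ValueError(
                    f"contact residue {label} must lie in "
                    f"{_FIRST_RES}..{H12_RANGE[0] - 1}"
                )
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"persistence for {label} outside [0, 1]")
        if self.noise_sigma_A < 0:
            raise ValueError("noise_sigma_A must be >= 0")
        if self.frame_interval_ps <= 0:
            raise ValueError("frame_interval_ps must be positive")
        if (self.n_basins > 1
                and self.basin_displacement_A <= 2 * self.noise_sigma_A):
            warnings.warn(
                "basin_displacement_A <= 2*noise_sigma_A: basins will "
                "overlap and may not be recoverable",
                stacklevel=2,
            )


@dataclass
class GroundTruth:
    """Planted per-frame labels and contact fractions for a generated
    trajectory."""

    basin_labels: np.ndarray  # int, one per frame
    displaced: np.ndarray  # bool, one per frame
    contact_fraction_planted: dict[str, float]
    contact_fraction_realized: dict[str, float]
    contact_type: dict[str, str]  # label -> "hbond" | "hydrophobic"
    seed: int


def _contact_residues(spec: SyntheticSpec) -> dict[int, tuple[str, str]]:
    """Map residue number -> (residue name, interaction type)."""
    out: dict[int, tuple[str, str]] = {}
    for label in sorted(spec.contact_persistence):
        name, num_s = _LABEL_RE.match(label).groups()
        num = int(num_s)
        last = _FIRST_RES + _N_RES - 1
        if not _FIRST_RES <= num <= last or H12_RANGE[0] <= num <= H12_RANGE[1]:
            raise ValueError(
                f"contact residue {label} must lie in "
                f"{_FIRST_RES}..{H12_RANGE[0] - 1}"
            )
        kind = "hbond" if label in spec.hbond_residues else "hydrophobic"
        out[num] = (name, kind)
    return out


def _reference_geometry(spec: SyntheticSpec):
    """Build the topology and reference coordinates (no noise, basin 0,
    H12 at its initial position, all contacts off)."""
    contacts = _contact_residues(spec)
    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    ca_by_residue: dict[int, int] = {}
    serial = 1
    for i in range(_N_RES):
        resnum = _FIRST_RES + i
        theta = i * _HELIX_TWIST
        ca = np.array([
            _HELIX_RADIUS * math.cos(theta),
            _HELIX_RADIUS * math.sin(theta),
            _HELIX_RISE * i,
        ])
        resname, kind = contacts.get(resnum, ("ALA", ""))
        # CA-trace scaffold: one alpha-carbon per residue (3.8 Å spacing,
        # compatible with a no-exclusion nonbonded evaluator)
        ca_by_residue[resnum] = len(atoms)
        atoms.append(Atom(serial, "CA", "C", resname, resnum, "A"))
        coords.append(ca)
        serial += 1
        if resnum in contacts:
            # side-chain marker; position is rewritten per frame
            name, element = (("OG", "O") if kind == "hbond" else ("CB", "C"))
            atoms.append(Atom(serial, name, element, resname, resnum, "A"))
            coords.append(ca.copy())
            serial += 1

    ref = np.array(coords)
    lbp_centroid = ref[[ca_by_residue[n] for n in LBP_RESIDUE_NUMBERS]].mean(0)

    # rigid 10-atom ring ligand outside the helix at pocket height; ring
    # spacing > 3 Å because the energy evaluator has no bonded exclusions
    lig_center = lbp_centroid + np.array([14.0, 0.0, 0.0])
    lig_coords = []
    for k in range(9):
        ang = 2 * math.pi * k / 9
        lig_coords.append(
            lig_center + 4.6 * np.array([math.cos(ang), math.sin(ang), 0.0])
        )
    lig_coords.append(lig_center + np.array([0.0, 0.0, 1.5]))
    lig_names = [f"C{k + 1}" for k in range(9)] + ["O1"]
    lig_elements = ["C"] * 9 + ["O"]
    for name, element, pos in zip(lig_names, lig_elements, lig_coords):
        atoms.append(Atom(serial, name, element, "LIG", 900, "A",
                          is_ligand=True))
        coords.append(np.asarray(pos))
        serial += 1

    return atoms, np.array(coords), ca_by_residue, contacts, lig_center


def generate_receptor_ligand_trajectory(
    spec: SyntheticSpec,
) -> tuple[Trajectory, GroundTruth]:
    """Generate a trajectory with planted basins, H12 states and contacts."""
    rng = np.random.default_rng(spec.seed)
    atoms, ref, ca_by_residue, contacts, lig_center = _reference_geometry(spec)
    n_atoms = len(atoms)
    n = spec.n_frames

    receptor_idx = np.array([i for i, a in enumerate(atoms) if not a.is_ligand])
    ligand_idx = np.array([i for i, a in enumerate(atoms) if a.is_ligand])
    marker_idx = {
        a.residue_number: i
        for i, a in enumerate(atoms)
        if a.name in ("CB", "OG") and not a.is_ligand
        and a.residue_number in contacts
    }
    h12_atoms = np.array([
        i for i, a in enumerate(atoms)
        if not a.is_ligand and H12_RANGE[0] <= a.residue_number <= H12_RANGE[1]
    ])
    loop_atoms = np.array([
        i for i, a in enumerate(atoms)
        if not a.is_ligand
        and _LOOP_RANGE[0] <= a.residue_number <= _LOOP_RANGE[1]
    ])
    noisy_idx = np.array(sorted(set(receptor_idx) - set(marker_idx.values())))

    # planted H12 direction: away from the pocket centroid
    lbp_centroid = ref[[ca_by_residue[r] for r in LBP_RESIDUE_NUMBERS]].mean(0)
    h12_centroid = ref[[ca_by_residue[r]
                        for r in range(H12_RANGE[0], H12_RANGE[1] + 1)]].mean(0)
    h12_dir = h12_centroid - lbp_centroid
    h12_dir = h12_dir / np.linalg.norm(h12_dir)

    # basin offsets applied to the mobile loop, random orthogonal-ish dirs
    basin_dirs = rng.standard_normal((spec.n_basins, 3))
    basin_dirs /= np.linalg.norm(basin_dirs, axis=1, keepdims=True)
    basin_offsets = spec.basin_displacement_A * basin_dirs
    basin_offsets[0] = 0.0  # basin 0 is the reference loop position

    # contiguous basin blocks sized by largest remainder of the weights
    raw = np.array(spec.basin_weights) * n
    sizes = np.floor(raw).astype(int)
    for k in np.argsort(-(raw - sizes))[: n - sizes.sum()]:
        sizes[k] += 1
    basin_labels = np.repeat(np.arange(spec.n_basins), sizes)

    displaced = rng.random(n) < spec.fraction_displaced
    displaced[0] = False  # frame 1 is the classification reference

    contact_on: dict[str, np.ndarray] = {}
    for label in sorted(spec.contact_persistence):
        contact_on[label] = rng.random(n) < spec.contact_persistence[label]

    noise = rng.standard_normal((n, len(noisy_idx), 3)) * spec.noise_sigma_A

    # contact marker anchors: cycle hydrophobic residues over ring carbons,
    # hbond residues anchor on the ligand oxygen
    ring_carbons = [i for i in ligand_idx if atoms[i].element == "C"]
    lig_oxygen = [i for i in ligand_idx if atoms[i].element == "O"][0]
    anchors: dict[str, int] = {}
    d_on: dict[str, float] = {}
    marker_dir: dict[str, np.ndarray] = {}
    k = 0
    for label in sorted(spec.contact_persistence):
        num = int(_LABEL_RE.match(label).group(2))
        if contacts[num][1] == "hbond":
            anchors[label] = lig_oxygen
            d_on[label] = 2.8
        else:
            anchors[label] = ring_carbons[k % len(ring_carbons)]
            d_on[label] = 3.5
        # marker direction: outward from the ligand body through its anchor
        # (never crosses the ring), with a small per-label tilt so markers
        # sharing an anchor cannot coincide
        u = ref[anchors[label]] - lig_center
        u = u / np.linalg.norm(u)
        u = u + 0.15 * k * np.array([0.0, 0.0, 1.0])
        marker_dir[label] = u / np.linalg.norm(u)
        k += 1

    frames: list[Frame] = []
    for t in range(n):
        xyz = ref.copy()
        xyz[loop_atoms] += basin_offsets[basin_labels[t]]
        # two-state switch (only active when displacement is planted):
        # displaced frames move outward, the rest sit inward of the
        # frame-1 reference so the sign rule separates the states cleanly
        if spec.fraction_displaced > 0 and t > 0:
            h12_shift = (spec.h12_displacement_A if displaced[t]
                         else -spec.h12_displacement_A)
            xyz[h12_atoms] += h12_shift * h12_dir
        xyz[noisy_idx] += noise[t]
        for label, on in contact_on.items():
            num = int(_LABEL_RE.match(label).group(2))
            dist = d_on[label] if on[t] else 9.0
            xyz[marker_idx[num]] = ref[anchors[label]] \
                + dist * marker_dir[label]
        frames.append(Frame(coordinates=xyz,
                            time_ps=t * spec.frame_interval_ps,
                            index=t + 1))

    trajectory = Trajectory(topology=atoms, frames=frames,
                            frame_interval_ps=spec.frame_interval_ps)
    truth = GroundTruth(
        basin_labels=basin_labels,
        displaced=displaced,
        contact_fraction_planted=dict(spec.contact_persistence),
        contact_fraction_realized={
            label: float(on.mean()) for label, on in contact_on.items()
        },
        contact_type={
            label: contacts[int(_LABEL_RE.match(label).group(2))][1]
            for label in spec.contact_persistence
        },
        seed=spec.seed,
    )
    return trajectory, truth


# ---------------------------------------------------------------------------
# toy parameterized systems for the energy evaluator


@dataclass
class ToyEnergySystem:
    """A small parameterized receptor + ligand pair; the complex is their
    union with the ligand in its bound pose."""

    receptor_coords: np.ndarray
    ligand_coords: np.ndarray
    receptor_params: AtomParameters
    ligand_params: AtomParameters

    @property
    def complex_coords(self) -> np.ndarray:
        return np.vstack([self.receptor_coords, self.ligand_coords])

    @property
    def complex_params(self) -> AtomParameters:
        return AtomParameters.concat(self.receptor_params, self.ligand_params)

    @property
    def n_atoms(self) -> int:
        return len(self.receptor_coords) + len(self.ligand_coords)


def generate_energy_toy_system(seed: int = 0, n_receptor: int = 40,
                               n_ligand: int = 10) -> ToyEnergySystem:
    """A random but well-spaced toy system (≤ 200 atoms) with finite
    charges, LJ parameters and Born radii for the energy evaluator."""
    if n_receptor + n_ligand > 200:
        raise ValueError("toy system limited to 200 atoms")
    rng = np.random.default_rng(seed)

    # receptor: points on a coarse helix, ~4.2 Å spacing (no LJ clashes)
    t = np.arange(n_receptor)
    receptor = np.column_stack([
        5.0 * np.cos(0.8 * t), 5.0 * np.sin(0.8 * t), 1.5 * t
    ])
    receptor += rng.normal(scale=0.15, size=receptor.shape)

    # ligand: ring near the receptor surface, spacing > 3 Å (the evaluator
    # treats every pair as nonbonded)
    center = receptor.mean(0) + np.array([14.0, 0.0, 0.0])
    ang = 2 * np.pi * np.arange(n_ligand) / n_ligand
    ligand = center + (1.7 * n_ligand / np.pi) * np.column_stack(
        [np.cos(ang), np.sin(ang), np.zeros(n_ligand)]
    )

    def params(m: int) -> AtomParameters:
        charge = rng.uniform(-0.3, 0.3, m)
        charge -= charge.mean()  # roughly neutral bodies
        return AtomParameters(
            charge=charge,
            sigma=rng.uniform(3.0, 3.6, m),
            epsilon=rng.uniform(0.05, 0.15, m),
            born_radius=rng.uniform(1.4, 2.0, m),
            hydrophobic=rng.random(m) < 0.6,
        )

    return ToyEnergySystem(
        receptor_coords=receptor,
        ligand_coords=ligand,
        receptor_params=params(n_receptor),
        ligand_params=params(n_ligand),
    )


def default_parameters(trajectory: Trajectory) -> AtomParameters:
    """Element-based toy parameters for a generated trajectory topology.

    A deliberately crude assignment: only the oxygens carry charge (the
    ligand hydroxyl oxygen +0.4 e as a united atom, receptor oxygens
    −0.4 e), carbons are apolar LJ spheres, nitrogens neutral — enough to
    make planted contacts energetically attractive while keeping both
    bodies near-neutral.
    """
    charge, sigma, epsilon, born, hydro = [], [], [], [], []
    for atom in trajectory.topology:
        el = atom.element.upper()
        if el == "O":
            q = 0.4 if atom.is_ligand else -0.4
            s, e, b, h = 3.0, 0.17, 1.5, False
        elif el == "N":
            q, s, e, b, h = 0.0, 3.25, 0.17, 1.55, False
        else:
            q, s, e, b, h = 0.0, 3.4, 0.11, 1.7, True
        charge.append(q)
        sigma.append(s)
        epsilon.append(e)
        born.append(b)
        hydro.append(h)
    return AtomParameters(
        charge=np.array(charge),
        sigma=np.array(sigma),
        epsilon=np.array(epsilon),
        born_radius=np.array(born),
        hydrophobic=np.array(hydro, dtype=bool),
    )
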