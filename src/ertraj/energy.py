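"""Simplified MM-GB/SA-style energy evaluator and the thermodynamic-cycle
binding free energy.

The free energy of a species (ligand, receptor, or complex) is the sum of
seven components — Coulomb, covalent, hydrogen-bond correction,
lipophilic, generalized-Born solvation, van der Waals, and pi–pi packing
correction — and the binding free energy follows the thermodynamic cycle

    ΔG_bind = E_complex − E_protein − E_ligand,

each species evaluated in implicit solvent with identical options.

The evaluator here is a transparent toy: all atom pairs are treated as
nonbonded, electrostatics use the bare Coulomb law with k = 332.0636
kcal·Å/(mol·e²), solvation uses the Still generalized-Born pairwise form
with fixed per-atom Born radii, the lipophilic term is γ·SASA over
hydrophobic atoms, and the covalent/H-bond/packing corrections are
weighted counts with zero default weights.  It is *not* a force field and
its absolute numbers are meaningful only for the synthetic systems in
this package; the component-sum and cycle arithmetic, however, are exact.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import Trajectory

__all__ = [
    "COULOMB_CONSTANT",
    "AtomParameters",
    "EnergyComponents",
    "BindingFreeEnergy",
    "EvaluatorOptions",
    "sum_components",
    "binding_free_energy",
    "single_point_energy",
    "trajectory_energy_profile",
    "BindingEnergyResult",
    "sasa",
]

#: electrostatic conversion constant, kcal·Å/(mol·e²)
COULOMB_CONSTANT = 332.0636


@dataclass
class AtomParameters:
    """Per-atom charges (e), LJ sigma (Å), LJ epsilon (kcal/mol), Born
    radii (Å) and hydrophobic flags."""

    charge: np.ndarray
    sigma: np.ndarray
    epsilon: np.ndarray
    born_radius: np.ndarray
    hydrophobic: np.ndarray

    def __post_init__(self) -> None:
        self.charge = np.asarray(self.charge, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.epsilon = np.asarray(self.epsilon, dtype=float)
        self.born_radius = np.asarray(self.born_radius, dtype=float)
        self.hydrophobic = np.asarray(self.hydrophobic, dtype=bool)
        n = len(self.charge)
        for name in ("sigma", "epsilon", "born_radius", "hydrophobic"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length != charge length")
        for name in ("sigma", "epsilon", "born_radius"):
            if np.any(getattr(self, name) <= 0):
                raise ValueError(f"{name} must be strictly positive")
        if not np.all(np.isfinite(self.charge)):
            raise ValueError("charges must be finite")

    def __len__(self) -> int:
        return len(self.charge)

    def subset(self, indices: np.ndarray) -> "AtomParameters":
        return AtomParameters(
            self.charge[indices], self.sigma[indices], self.epsilon[indices],
            self.born_radius[indices], self.hydrophobic[indices],
        )

    @staticmethod
    def concat(a: "AtomParameters", b: "AtomParameters") -> "AtomParameters":
        return AtomParameters(
            np.concatenate([a.charge, b.charge]),
            np.concatenate([a.sigma, b.sigma]),
            np.concatenate([a.epsilon, b.epsilon]),
            np.concatenate([a.born_radius, b.born_radius]),
            np.concatenate([a.hydrophobic, b.hydrophobic]),
        )


@dataclass(frozen=True)
class EnergyComponents:
    """The seven per-species energy terms, kcal/mol."""

    coulomb: float = 0.0
    covalent: float = 0.0
    hbond: float = 0.0
    lipo: float = 0.0
    solv_gb: float = 0.0
    vdw: float = 0.0
    packing: float = 0.0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if not np.isfinite(getattr(self, f.name)):
                raise ValueError(f"non-finite component {f.name}")

    def __sub__(self, other: "EnergyComponents") -> "EnergyComponents":
        return EnergyComponents(*[
            getattr(self, f.name) - getattr(other, f.name)
            for f in dataclasses.fields(self)
        ])

    def __add__(self, other: "EnergyComponents") -> "EnergyComponents":
        return EnergyComponents(*[
            getattr(self, f.name) + getattr(other, f.name)
            for f in dataclasses.fields(self)
        ])


def sum_components(c: EnergyComponents) -> float:
    """Total free energy of a species: the plain sum of its seven terms."""
    return (c.coulomb + c.covalent + c.hbond + c.lipo + c.solv_gb + c.vdw
            + c.packing)


@dataclass(frozen=True)
class BindingFreeEnergy:
    """Thermodynamic-cycle result; ``delta_g_bind`` always equals
    ``e_complex − e_protein − e_ligand``."""

    e_complex: float
    e_protein: float
    e_ligand: float
    delta_g_bind: float


def binding_free_energy(
    e_complex: float, e_protein: float, e_ligand: float
) -> BindingFreeEnergy:
    """ΔG_bind = E_complex − E_protein − E_ligand (all kcal/mol)."""
    values = (e_complex, e_protein, e_ligand)
    if not all(np.isfinite(v) for v in values):
        raise ValueError("energies must be finite")
    return BindingFreeEnergy(
        e_complex=float(e_complex),
        e_protein=float(e_protein),
        e_ligand=float(e_ligand),
        delta_g_bind=float(e_complex) - float(e_protein) - float(e_ligand),
    )


@dataclass(frozen=True)
class EvaluatorOptions:
    """Knobs of the single-point evaluator.

    ``dielectric_in``/``dielectric_out`` are the solute/solvent dielectric
    constants of the generalized-Born term; ``surface_tension`` (kcal/mol/Å²)
    scales the hydrophobic SASA; the three correction weights default to 0
    so those components are exercised but vanish unless enabled.
    """

    dielectric_in: float = 1.0
    dielectric_out: float = 78.5
    distance_dependent_dielectric: bool = False
    surface_tension: float = 0.0072
    probe_radius_A: float = 1.4
    n_sphere_points: int = 960
    hbond_weight: float = 0.0
    hbond_distance_A: float = 3.5
    covalent_weight: float = 0.0
    covalent_distance_A: float = 1.8
    packing_weight: float = 0.0
    packing_distance_A: float = 4.5


_SPHERE_CACHE: dict[int, np.ndarray] = {}


def _unit_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden-spiral
    lattice), cached per point count."""
    if n not in _SPHERE_CACHE:
        k = np.arange(n) + 0.5
        phi = np.arccos(1.0 - 2.0 * k / n)
        theta = np.pi * (1.0 + 5.0 ** 0.5) * k
        _SPHERE_CACHE[n] = np.column_stack([
            np.cos(theta) * np.sin(phi),
            np.sin(theta) * np.sin(phi),
            np.cos(phi),
        ])
    return _SPHERE_CACHE[n]


def sasa(
    coordinates: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Å²) by sphere sampling.

    Each atom's sphere of radius ``r_i + probe`` is sampled on a
    golden-spiral lattice; the accessible fraction is the share of points
    outside every other atom's expanded sphere.
    """
    coordinates = np.asarray(coordinates, dtype=float)
    radii = np.asarray(radii, dtype=float) + probe_radius
    n = len(coordinates)
    points = _unit_sphere(n_points)
    areas = np.empty(n)
    if n > 1:
        diff = coordinates[:, None, :] - coordinates[None, :, :]
        dist = np.sqrt((diff ** 2).sum(-1))
    for i in range(n):
        sphere = coordinates[i] + radii[i] * points
        accessible = np.ones(n_points, dtype=bool)
        if n > 1:
            neighbors = np.where(
                (dist[i] < radii[i] + radii) & (np.arange(n) != i)
            )[0]
            for j in neighbors:
                d2 = ((sphere - coordinates[j]) ** 2).sum(1)
                accessible &= d2 > radii[j] ** 2
        areas[i] = 4.0 * np.pi * radii[i] ** 2 * accessible.mean()
    return areas


def single_point_energy(
    coordinates: np.ndarray,
    params: AtomParameters,
    options: EvaluatorOptions = EvaluatorOptions(),
) -> EnergyComponents:
    """Evaluate the seven components for one set of coordinates.

    Coulomb: Σ_{i<j} k·q_i·q_j / (ε_r·r_ij), ε_r = r_ij when the
    distance-dependent dielectric is on, else ε_in.
    vdW: Lennard-Jones 12-6 with Lorentz–Berthelot combining rules.
    Solvation: Still pairwise generalized Born,
    −(k/2)·(1/ε_in − 1/ε_out)·Σ_i Σ_j q_i q_j / f_GB with
    f_GB = sqrt(r² + a_i·a_j·exp(−r²/(4·a_i·a_j))) over ordered pairs
    (the i = j self terms give the Born ion limit).
    Lipophilic: γ·SASA over hydrophobic atoms.  The covalent, H-bond and
    packing corrections are distance-thresholded pair counts times their
    weights (zero by default).
    """
    coordinates = np.asarray(coordinates, dtype=float)
    if coordinates.ndim != 2 or coordinates.shape[1] != 3:
        raise ValueError("coordinates must have shape (n_atoms, 3)")
    n = len(coordinates)
    if len(params) != n:
        raise ValueError(
            f"parameters cover {len(params)} atoms, coordinates have {n}"
        )

    q = params.charge
    iu, ju = np.triu_indices(n, k=1)
    if len(iu):
        r = np.sqrt(((coordinates[iu] - coordinates[ju]) ** 2).sum(1))
        if np.any(r < 1e-9):
            raise ValueError("coincident atoms in energy evaluation")
        qq = q[iu] * q[ju]
        eps_r = r if options.distance_dependent_dielectric \
            else options.dielectric_in
        coulomb = float(np.sum(COULOMB_CONSTANT * qq / (eps_r * r)))

        sig = 0.5 * (params.sigma[iu] + params.sigma[ju])
        eps = np.sqrt(params.epsilon[iu] * params.epsilon[ju])
        sr6 = (sig / r) ** 6
        vdw = float(np.sum(4.0 * eps * (sr6 ** 2 - sr6)))
    else:
        r = np.empty(0)
        coulomb = 0.0
        vdw = 0.0

    # generalized Born over ordered pairs: self terms once, cross twice
    tau = 1.0 / options.dielectric_in - 1.0 / options.dielectric_out
    a = params.born_radius
    gb = float(np.sum(q * q / a))  # i == j: f_GB = a_i
    if len(iu):
        aa = a[iu] * a[ju]
        f_gb = np.sqrt(r ** 2 + aa * np.exp(-(r ** 2) / (4.0 * aa)))
        gb += 2.0 * float(np.sum(qq / f_gb))
    solv_gb = -0.5 * COULOMB_CONSTANT * tau * gb

    if options.surface_tension != 0.0 and np.any(params.hydrophobic):
        areas = sasa(coordinates, params.sigma / 2.0,
                     options.probe_radius_A, options.n_sphere_points)
        lipo = options.surface_tension * float(areas[params.hydrophobic].sum())
    else:
        lipo = 0.0

    def _count(cutoff: float) -> int:
        return int(np.count_nonzero(r <= cutoff)) if len(iu) else 0

    covalent = options.covalent_weight * _count(options.covalent_distance_A)
    hbond = options.hbond_weight * _count(options.hbond_distance_A)
    packing = options.packing_weight * _count(options.packing_distance_A)

    return EnergyComponents(
        coulomb=coulomb, covalent=covalent, hbond=hbond, lipo=lipo,
        solv_gb=solv_gb, vdw=vdw, packing=packing,
    )


@dataclass(frozen=True)
class BindingEnergyResult:
    """Energies for one frame of a trajectory: per-species components,
    their totals, and the cycle ΔG with component-wise deltas."""

    frame_index: int
    complex_components: EnergyComponents
    receptor_components: EnergyComponents
    ligand_components: EnergyComponents
    binding: BindingFreeEnergy

    @property
    def delta_components(self) -> EnergyComponents:
        return (self.complex_components - self.receptor_components
                - self.ligand_components)


def trajectory_energy_profile(
    trajectory: Trajectory,
    params: AtomParameters,
    representatives: Sequence[int],
    options: EvaluatorOptions = EvaluatorOptions(),
) -> list[BindingEnergyResult]:
    """Evaluate the binding cycle on selected frames (1-based indices).

    Each frame is split into receptor and ligand by the topology's
    ``is_ligand`` flags; complex, receptor-alone and ligand-alone energies
    use identical options.
    """
    if not representatives:
        raise ValueError("representatives must be non-empty")
    if len(params) != trajectory.n_atoms:
        raise ValueError("parameters do not cover the trajectory topology")
    rec_idx = trajectory.receptor_indices()
    lig_idx = trajectory.ligand_indices()
    if len(lig_idx) == 0:
        raise ValueError("trajectory has no ligand atoms")
    rec_params = params.subset(rec_idx)
    lig_params = params.subset(lig_idx)
    by_index = {f.index: f for f in trajectory.frames}

    results = []
    for idx in representatives:
        if idx not in by_index:
            raise KeyError(f"frame {idx} not in trajectory")
        xyz = by_index[idx].coordinates
        c_complex = single_point_energy(xyz, params, options)
        c_rec = single_point_energy(xyz[rec_idx], rec_params, options)
        c_lig = single_point_energy(xyz[lig_idx], lig_params, options)
        binding = binding_free_energy(
            sum_components(c_complex), sum_components(c_rec),
            sum_components(c_lig),
        )
        results.append(BindingEnergyResult(
            frame_index=idx,
            complex_components=c_complex,
            receptor_components=c_rec,
            ligand_components=c_lig,
            binding=binding,
        ))
    return results
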