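"""Domain types for protein–ligand trajectories and residue selections.

Coordinates are in Å, times in ps, energies in kcal/mol throughout the
package.  Frame indices are 1-based in every report and public field, the
convention used when citing individual structures from a simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Frame",
    "Trajectory",
    "AtomMode",
    "ResidueSelection",
    "SelectionError",
    "resolve_selection",
]

#: residue names treated as water and never as the bound ligand
WATER_RESNAMES = frozenset({"HOH", "WAT"})


class SelectionError(ValueError):
    """A residue selection could not be resolved against a topology."""


@dataclass(frozen=True)
class Atom:
    """One atom of the topology.

    ``residue_number`` together with ``chain_id`` identifies a residue;
    ``is_ligand`` marks atoms of the bound small molecule (HETATM records
    that are not water).
    """

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    is_ligand: bool = False

    @property
    def residue_key(self) -> tuple[str, int]:
        return (self.chain_id, self.residue_number)


@dataclass
class Frame:
    """One recorded structure: coordinates for every topology atom."""

    coordinates: np.ndarray  # (n_atoms, 3) float64, Å
    time_ps: float
    index: int  # 1-based

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=np.float64)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError(f"frame {self.index}: non-finite coordinates")


@dataclass
class Trajectory:
    """An ordered list of frames sharing one topology.

    Invariants: every frame has exactly one coordinate triple per topology
    atom; frame indices are strictly increasing starting at 1;
    ``frame_interval_ps`` is positive.
    """

    topology: list[Atom]
    frames: list[Frame]
    frame_interval_ps: float = 4.8

    def __post_init__(self) -> None:
        if self.frame_interval_ps <= 0:
            raise ValueError("frame_interval_ps must be positive")
        n = len(self.topology)
        for f in self.frames:
            if f.coordinates.shape[0] != n:
                raise ValueError(
                    f"frame {f.index} has {f.coordinates.shape[0]} atoms, "
                    f"topology has {n}"
                )
        indices = [f.index for f in self.frames]
        if indices and (indices[0] != 1 or any(
                b <= a for a, b in zip(indices, indices[1:]))):
            raise ValueError("frame indices must strictly increase from 1")

    @property
    def n_atoms(self) -> int:
        return len(self.topology)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def __len__(self) -> int:
        return self.n_frames

    def __iter__(self) -> Iterator[Frame]:
        return iter(self.frames)

    def coordinate_array(self) -> np.ndarray:
        """Stack all frame coordinates into an (n_frames, n_atoms, 3) array."""
        return np.stack([f.coordinates for f in self.frames])

    def ligand_indices(self) -> np.ndarray:
        return np.array(
            [i for i, a in enumerate(self.topology) if a.is_ligand], dtype=int
        )

    def receptor_indices(self) -> np.ndarray:
        return np.array(
            [i for i, a in enumerate(self.topology) if not a.is_ligand],
            dtype=int,
        )


class AtomMode(str, Enum):
    """Which atoms of each selected residue contribute."""

    CA_ONLY = "CA_ONLY"
    HEAVY = "HEAVY"
    ALL = "ALL"


@dataclass
class ResidueSelection:
    """A labelled set of residues, e.g. the 17-residue LBP centroid set or
    the helix-12 segment (Asp535–Leu549)."""

    label: str
    members: Sequence[tuple[str, int]]  # (chain_id, residue_number)
    atom_mode: AtomMode = AtomMode.CA_ONLY

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"selection {self.label!r}: members empty")
        if len(set(self.members)) != len(list(self.members)):
            raise ValueError(f"selection {self.label!r}: duplicate members")
        self.atom_mode = AtomMode(self.atom_mode)

    @classmethod
    def from_range(
        cls,
        label: str,
        chain_id: str,
        start: int,
        stop: int,
        atom_mode: AtomMode = AtomMode.CA_ONLY,
    ) -> "ResidueSelection":
        """Selection spanning residues ``start``..``stop`` inclusive."""
        return cls(label, [(chain_id, r) for r in range(start, stop + 1)],
                   atom_mode)


def _is_hydrogen(atom: Atom) -> bool:
    el = atom.element.strip().upper()
    if el:
        return el == "H" or el == "D"
    return atom.name.strip().startswith("H")


def resolve_selection(
    trajectory: Trajectory, selection: ResidueSelection
) -> np.ndarray:
    """Map a residue selection to sorted topology atom indices.

    ``CA_ONLY`` keeps one alpha-carbon per residue, ``HEAVY`` drops
    hydrogens, ``ALL`` keeps everything.  Raises :class:`SelectionError`
    listing every member that does not resolve to at least one atom.
    """
    by_residue: dict[tuple[str, int], list[int]] = {}
    for i, atom in enumerate(trajectory.topology):
        by_residue.setdefault(atom.residue_key, []).append(i)

    indices: list[int] = []
    missing: list[tuple[str, int]] = []
    for member in selection.members:
        atom_ids = by_residue.get(member)
        if not atom_ids:
            missing.append(member)
            continue
        if selection.atom_mode is AtomMode.CA_ONLY:
            ca = [i for i in atom_ids
                  if trajectory.topology[i].name.strip() == "CA"]
            if not ca:
                missing.append(member)
                continue
            indices.extend(ca[:1])
        elif selection.atom_mode is AtomMode.HEAVY:
            heavy = [i for i in atom_ids
                     if not _is_hydrogen(trajectory.topology[i])]
            if not heavy:
                missing.append(member)
                continue
            indices.extend(heavy)
        else:
            indices.extend(atom_ids)

    if missing:
        pretty = ", ".join(f"{c}:{n}" for c, n in missing)
        raise SelectionError(
            f"selection {selection.label!r}: unresolvable residues: {pretty}"
        )
    return np.array(sorted(set(indices)), dtype=int)
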