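"""Multi-model PDB reading and writing.

A trajectory is stored as a standard multi-model PDB file: MODEL/ENDMDL
blocks delimit frames, the first model defines the topology, and ligand
atoms are HETATM records (water excluded from ligand detection).  Parsing
is delegated to Biopython; writing emits standard 80-column records.

Limitations: insertion codes are rejected; for alternate locations the
highest-occupancy conformer is kept (first on tie, Biopython's rule).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.Atom import DisorderedAtom

from .core import WATER_RESNAMES, Atom, Frame, Trajectory

__all__ = ["PDBFormatError", "read_multimodel_pdb", "write_multimodel_pdb"]


class PDBFormatError(ValueError):
    """The PDB file violates the multi-model trajectory contract."""


def _model_atoms(model):
    """Atoms of a model in file order, one conformer per disordered atom."""
    atoms = []
    for chain in model:
        for residue in chain:
            het, resseq, icode = residue.id
            if icode and icode.strip():
                raise PDBFormatError(
                    f"insertion code {icode!r} at residue "
                    f"{residue.resname}{resseq} is not supported"
                )
            for atom in residue:
                if isinstance(atom, DisorderedAtom):
                    atom = atom.selected_child  # highest occupancy
                atoms.append((chain.id, residue, atom))
    return atoms


def read_multimodel_pdb(
    path: str | Path, frame_interval_ps: float = 4.8
) -> Trajectory:
    """Read a multi-model PDB file into a :class:`Trajectory`.

    The first model defines the topology; every model must contain the
    same atoms in the same order.  Frame times are assigned as
    ``(i - 1) * frame_interval_ps``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure(path.stem, str(path))
    models = list(structure)
    if not models:
        raise PDBFormatError(f"{path}: no models found")

    first = _model_atoms(models[0])
    topology: list[Atom] = []
    for chain_id, residue, atom in first:
        het = residue.id[0]
        is_het = het.strip() != "" if isinstance(het, str) else False
        resname = residue.resname.strip()
        topology.append(
            Atom(
                serial=int(atom.serial_number or len(topology) + 1),
                name=atom.name,
                element=(atom.element or "").strip(),
                residue_name=resname,
                residue_number=int(residue.id[1]),
                chain_id=chain_id,
                is_ligand=is_het and resname not in WATER_RESNAMES,
            )
        )

    frames: list[Frame] = []
    n = len(topology)
    for m, model in enumerate(models, start=1):
        atoms = _model_atoms(model) if m > 1 else first
        if len(atoms) != n:
            raise PDBFormatError(
                f"{path}: model {m} has {len(atoms)} atoms, "
                f"model 1 has {n}"
            )
        coords = np.array([a.coord for _, _, a in atoms], dtype=np.float64)
        frames.append(
            Frame(coordinates=coords, time_ps=(m - 1) * frame_interval_ps,
                  index=m)
        )
    return Trajectory(topology=topology, frames=frames,
                      frame_interval_ps=frame_interval_ps)


def _format_atom_name(name: str, element: str) -> str:
    # columns 13-16: one/two-letter elements start at column 14 unless the
    # name already fills four characters
    name = name.strip()
    if len(name) >= 4:
        return name[:4]
    if len(element.strip()) == 2:
        return f"{name:<4s}"
    return f" {name:<3s}"


def write_multimodel_pdb(trajectory: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB file (one MODEL per frame)."""
    if trajectory.n_frames == 0:
        raise ValueError("cannot write a trajectory with zero frames")
    path = Path(path)
    lines: list[str] = []
    for frame in trajectory.frames:
        lines.append(f"MODEL     {frame.index:4d}")
        for atom, xyz in zip(trajectory.topology, frame.coordinates):
            record = "HETATM" if atom.is_ligand else "ATOM  "
            name = _format_atom_name(atom.name, atom.element)
            lines.append(
                f"{record}{atom.serial:5d} {name} "
                f"{atom.residue_name:>3s} {atom.chain_id:1s}"
                f"{atom.residue_number:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          "
                f"{atom.element.strip():>2s}"
            )
        lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
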