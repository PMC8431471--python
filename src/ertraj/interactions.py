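"""Ligand–residue interaction detection and persistence profiles.

For every frame, hydrogen bonds (donor/acceptor N or O heavy atoms within
a distance cutoff, plus a D–H···A angle criterion when hydrogens are
present) and hydrophobic contacts (carbon–carbon pairs within a cutoff)
are detected between the ligand and the receptor.  A residue–ligand pair
counts at most once per frame per interaction type; the persistence of an
interaction is the fraction of frames in which it is present — the
"fraction of simulation time" bars of standard interaction diagrams.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Atom, Frame, Trajectory

__all__ = [
    "HBondCriteria",
    "InteractionCriteria",
    "InteractionProfile",
    "detect_hbonds",
    "detect_hydrophobic",
    "persistence_profile",
    "write_profile",
]

HBOND_ELEMENTS = frozenset({"N", "O"})


@dataclass(frozen=True)
class HBondCriteria:
    """Heavy-atom distance cutoff (Å) and minimum D–H···A angle (degrees);
    the angle test is skipped when no hydrogens are present."""

    d_max_A: float = 3.5
    angle_min_deg: float = 120.0


@dataclass(frozen=True)
class InteractionCriteria:
    hbond: HBondCriteria = HBondCriteria()
    hydrophobic_cutoff_A: float = 4.5


@dataclass
class InteractionProfile:
    """Per-residue interaction persistence.

    ``data`` columns: residue_name, residue_number, chain_id,
    interaction_type, n_frames_present, fraction.  Residues never seen
    interacting are omitted.
    """

    data: pd.DataFrame
    total_frames: int

    def fraction(self, residue_number: int, interaction_type: str) -> float:
        rows = self.data[
            (self.data.residue_number == residue_number)
            & (self.data.interaction_type == interaction_type)
        ]
        return float(rows.fraction.iloc[0]) if len(rows) else 0.0


def _attached_hydrogens(topology: list[Atom], coords: np.ndarray,
                        heavy_index: int) -> np.ndarray:
    """Hydrogens of the same residue within covalent range of a heavy atom."""
    heavy = topology[heavy_index]
    out = []
    for i, atom in enumerate(topology):
        if atom.element.upper() != "H":
            continue
        if atom.residue_key != heavy.residue_key:
            continue
        if np.linalg.norm(coords[i] - coords[heavy_index]) <= 1.25:
            out.append(i)
    return np.array(out, dtype=int)


def detect_hbonds(
    frame: Frame,
    trajectory: Trajectory,
    criteria: HBondCriteria = HBondCriteria(),
) -> list[tuple[int, tuple[str, int]]]:
    """Hydrogen-bonded (ligand atom index, residue key) pairs in a frame.

    Polar heavy atoms (N, O) of the ligand are paired against polar heavy
    atoms of the receptor.  When either partner has attached hydrogens the
    D–H···A angle must also pass; with no hydrogens (coarse models) the
    distance criterion alone decides, the common convention for
    heavy-atom-only topologies.
    """
    topo = trajectory.topology
    coords = frame.coordinates
    lig = [i for i, a in enumerate(topo)
           if a.is_ligand and a.element.upper() in HBOND_ELEMENTS]
    rec = [i for i, a in enumerate(topo)
           if not a.is_ligand and a.element.upper() in HBOND_ELEMENTS]
    found = []
    for i in lig:
        for j in rec:
            d = float(np.linalg.norm(coords[i] - coords[j]))
            if d > criteria.d_max_A or d < 1e-6:
                continue
            if not _angle_ok(topo, coords, i, j, criteria.angle_min_deg):
                continue
            found.append((i, topo[j].residue_key))
    return found


def _angle_ok(topology, coords, i, j, angle_min_deg) -> bool:
    """D–H···A angle check for either direction; True when no hydrogens."""
    for donor, acceptor in ((i, j), (j, i)):
        hydrogens = _attached_hydrogens(topology, coords, donor)
        for h in hydrogens:
            dh = coords[donor] - coords[h]
            ah = coords[acceptor] - coords[h]
            cosang = np.dot(dh, ah) / (
                np.linalg.norm(dh) * np.linalg.norm(ah) + 1e-12
            )
            angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            if angle >= angle_min_deg:
                return True
        if len(hydrogens):
            # this direction has hydrogens but none passes; try the other
            continue
    any_h = (len(_attached_hydrogens(topology, coords, i))
             + len(_attached_hydrogens(topology, coords, j)))
    return any_h == 0


def detect_hydrophobic(
    frame: Frame,
    trajectory: Trajectory,
    cutoff_A: float = 4.5,
) -> list[tuple[int, tuple[str, int]]]:
    """Hydrophobic (ligand atom index, residue key) pairs: carbon–carbon
    within the cutoff; each residue appears once per qualifying ligand
    atom pairing but is collapsed per residue downstream."""
    topo = trajectory.topology
    coords = frame.coordinates
    lig = np.array([i for i, a in enumerate(topo)
                    if a.is_ligand and a.element.upper() == "C"], dtype=int)
    rec = np.array([i for i, a in enumerate(topo)
                    if not a.is_ligand and a.element.upper() == "C"],
                   dtype=int)
    if len(lig) == 0 or len(rec) == 0:
        return []
    d = np.linalg.norm(
        coords[lig][:, None, :] - coords[rec][None, :, :], axis=2
    )
    found = []
    seen = set()
    for li, rj in zip(*np.nonzero(d <= cutoff_A)):
        key = (int(lig[li]), topo[rec[rj]].residue_key)
        if key not in seen:
            seen.add(key)
            found.append(key)
    return found


def persistence_profile(
    trajectory: Trajectory,
    criteria: InteractionCriteria = InteractionCriteria(),
) -> InteractionProfile:
    """Fraction of frames in which each residue interacts with the ligand,
    per interaction type.  A residue counts at most once per frame per
    type; residues with zero occupancy are suppressed."""
    if trajectory.n_frames < 1:
        raise ValueError("trajectory has no frames")
    resname = {a.residue_key: a.residue_name for a in trajectory.topology
               if not a.is_ligand}
    counts: dict[tuple[tuple[str, int], str], int] = {}
    for frame in trajectory.frames:
        hb = {res for _, res in detect_hbonds(frame, trajectory,
                                              criteria.hbond)}
        hp = {res for _, res in detect_hydrophobic(
            frame, trajectory, criteria.hydrophobic_cutoff_A)}
        for res in hb:
            counts[(res, "hbond")] = counts.get((res, "hbond"), 0) + 1
        for res in hp:
            counts[(res, "hydrophobic")] = counts.get(
                (res, "hydrophobic"), 0) + 1
    total = trajectory.n_frames
    rows = [
        {
            "residue_name": resname[res],
            "residue_number": res[1],
            "chain_id": res[0],
            "interaction_type": kind,
            "n_frames_present": n,
            "fraction": n / total,
        }
        for (res, kind), n in counts.items()
    ]
    data = pd.DataFrame(
        rows,
        columns=["residue_name", "residue_number", "chain_id",
                 "interaction_type", "n_frames_present", "fraction"],
    ).sort_values(
        ["residue_number", "interaction_type"]
    ).reset_index(drop=True)
    return InteractionProfile(data=data, total_frames=total)


def write_profile(profile: InteractionProfile, path: str | Path) -> None:
    """CSV: residue, residue_number, type, n_frames, fraction (4 dp)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["residue_name", "residue_number", "chain_id",
                         "interaction_type", "n_frames_present", "fraction"])
        for row in profile.data.itertuples(index=False):
            writer.writerow([
                row.residue_name, row.residue_number, row.chain_id,
                row.interaction_type, row.n_frames_present,
                f"{row.fraction:.4f}",
            ])
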