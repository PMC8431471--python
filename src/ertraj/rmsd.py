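"""Optimal rigid-body superposition and all-vs-all frame RMSD matrices.

The RMSD between two frames is minimized over all proper rotations and
translations (Kabsch algorithm via SVD, reflections excluded), computed
on a configurable atom selection — by convention the alpha-carbons of the
receptor.  The all-vs-all matrix over the frames of a trajectory is the
input to hierarchical conformational clustering and, plotted as a heat
map, shows the block structure of a multi-basin ensemble.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import ResidueSelection, Trajectory, resolve_selection

__all__ = ["RMSDMatrix", "kabsch_rmsd", "pairwise_rmsd", "export_matrix",
           "load_matrix"]

#: default hard cap on frames entering the O(n²) matrix
DEFAULT_MAX_FRAMES = 5000


@dataclass
class RMSDMatrix:
    """Symmetric matrix of minimized RMSD values (Å) between frames.

    ``frame_indices`` are the 1-based trajectory frame indices retained
    after striding; ``values[i, j]`` is the RMSD between the frames at
    positions i and j of that list.
    """

    values: np.ndarray
    frame_indices: np.ndarray
    selection_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.frame_indices = np.asarray(self.frame_indices, dtype=int)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("values must be square")
        if v.shape[0] != len(self.frame_indices):
            raise ValueError("frame_indices length mismatch")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValueError("RMSD values must be finite and non-negative")
        if np.any(np.diagonal(v) != 0.0):
            raise ValueError("diagonal must be exactly zero")
        if not np.array_equal(v, v.T):
            raise ValueError("matrix must be symmetric")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def position_of(self, frame_index: int) -> int:
        pos = np.nonzero(self.frame_indices == frame_index)[0]
        if len(pos) == 0:
            raise KeyError(f"frame {frame_index} not in matrix")
        return int(pos[0])


def kabsch_rmsd(
    coords_a: np.ndarray, coords_b: np.ndarray
) -> tuple[float, np.ndarray]:
    """Minimum RMSD between two paired point sets and the optimal rotation.

    Returns ``(rmsd, R)`` where ``R`` (det +1) is the proper rotation that,
    applied to the centered first set, best superposes it on the centered
    second set.  Reflections are excluded by the standard determinant
    correction.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"point counts differ: {a.shape} vs {b.shape}")
    if a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("point sets must have shape (n, 3)")
    n = a.shape[0]
    if n < 3:
        raise ValueError("at least 3 points are required")
    ac = a - a.mean(0)
    bc = b - b.mean(0)
    if np.allclose(ac, 0) and np.allclose(bc, 0):
        raise ValueError("points are all coincident")

    h = ac.T @ bc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.array([1.0, 1.0, d])
    rotation = vt.T @ np.diag(corr) @ u.T
    ssa = (ac ** 2).sum()
    ssb = (bc ** 2).sum()
    msd = (ssa + ssb - 2.0 * (s * corr).sum()) / n
    # snap cancellation noise (identical shapes) to an exact zero
    if msd < 1e-12 * (ssa + ssb) / n:
        msd = 0.0
    return float(np.sqrt(max(msd, 0.0))), rotation


def _pairwise_from_coords(coords: np.ndarray) -> np.ndarray:
    """All-vs-all minimized RMSD from an (n_frames, n_atoms, 3) stack,
    computed row-blockwise with batched 3×3 SVDs."""
    n, m, _ = coords.shape
    centered = coords - coords.mean(axis=1, keepdims=True)
    ss = (centered ** 2).sum(axis=(1, 2))
    out = np.zeros((n, n))
    for i in range(n - 1):
        rest = centered[i + 1:]
        h = np.einsum("ka,jkb->jab", centered[i], rest)
        s = np.linalg.svd(h, compute_uv=False)
        sign = np.sign(np.linalg.det(h))
        sign[sign == 0] = 1.0
        trace = s[:, 0] + s[:, 1] + sign * s[:, 2]
        msd = (ss[i] + ss[i + 1:] - 2.0 * trace) / m
        # snap cancellation noise (identical shapes) to an exact zero
        msd[msd < 1e-12 * (ss[i] + ss[i + 1:]) / m] = 0.0
        out[i, i + 1:] = np.sqrt(np.clip(msd, 0.0, None))
    return out + out.T


def pairwise_rmsd(
    trajectory: Trajectory,
    selection: ResidueSelection,
    stride: int = 1,
    max_frames: int | None = DEFAULT_MAX_FRAMES,
) -> RMSDMatrix:
    """All-vs-all minimized RMSD over the selected atoms of a trajectory.

    Frames are thinned by ``stride`` first; the O(n²) cost is guarded by
    ``max_frames`` (pass ``None`` to lift the cap for long runs).
    """
    if stride < 1:
        raise ValueError("stride must be a positive integer")
    if stride >= trajectory.n_frames:
        raise ValueError("stride must be smaller than the frame count")
    atom_idx = resolve_selection(trajectory, selection)
    if len(atom_idx) == 0:
        raise ValueError("selection resolves to no atoms")
    frames = trajectory.frames[::stride]
    if len(frames) < 2:
        raise ValueError("fewer than 2 frames after striding")
    if max_frames is not None and len(frames) > max_frames:
        raise ValueError(
            f"{len(frames)} frames exceed max_frames={max_frames} "
            f"({len(frames) * (len(frames) - 1) // 2} pairs); increase the "
            "stride or raise the cap"
        )
    coords = np.stack([f.coordinates[atom_idx] for f in frames])
    values = _pairwise_from_coords(coords)
    return RMSDMatrix(
        values=values,
        frame_indices=np.array([f.index for f in frames]),
        selection_label=selection.label,
    )


def export_matrix(matrix: RMSDMatrix, path: str | Path) -> None:
    """Write the matrix as CSV: header row/column of frame indices, values
    to 4 decimals."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame"] + [str(i) for i in matrix.frame_indices])
        for idx, row in zip(matrix.frame_indices, matrix.values):
            writer.writerow([str(idx)] + [f"{v:.4f}" for v in row])


def load_matrix(path: str | Path, selection_label: str = "") -> RMSDMatrix:
    """Read a matrix written by :func:`export_matrix`."""
    path = Path(path)
    with path.open(newline="") as fh:
        rows = list(csv.reader(fh))
    header = [int(x) for x in rows[0][1:]]
    values = np.array([[float(x) for x in row[1:]] for row in rows[1:]])
    # symmetrize away 4-decimal print asymmetry, if any, and zero diagonal
    values = 0.5 * (values + values.T)
    np.fill_diagonal(values, 0.0)
    return RMSDMatrix(values=values, frame_indices=np.array(header),
                      selection_label=selection_label)
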