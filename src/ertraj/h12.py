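"""The helix-12 conformational-switch statistic.

In the estrogen-receptor ligand-binding domain, helix 12 (H12) packs
against the pocket in the transcriptionally active (agonist-bound) form
and swings outward in the inactive (antagonist-bound) form.  The switch
is quantified per frame as the *maximum* distance from any H12 residue to
the centroid of a fixed set of ligand-binding-pocket (LBP) residues,
expressed relative to the first frame:

* relative distance > 0 — H12 farther out than initially → inactive-like,
* relative distance < 0 — H12 closer in → active-like,
* |relative distance| ≤ threshold — counted with the initial form.

The populations of the two forms give an activation free energy through
ΔG = −RT·ln(N_active / N_inactive).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Frame, ResidueSelection, Trajectory, resolve_selection

__all__ = [
    "GAS_CONSTANT_KCAL",
    "H12Profile",
    "lbp_centroid",
    "h12_distance",
    "relative_distance_series",
    "classify_forms",
    "activation_energy",
]

#: gas constant, kcal mol⁻¹ K⁻¹
GAS_CONSTANT_KCAL = 1.9872e-3

ACTIVE = "active"
INACTIVE = "inactive"


@dataclass
class H12Profile:
    """Per-frame H12 distances and (once classified) form labels.

    ``data`` columns: frame, time_ps, h12_distance_A, relative_distance_A,
    and after :func:`classify_forms` also label.  ``delta_g_kcal_mol`` is
    set when both populations are non-empty.
    """

    data: pd.DataFrame
    initial_form: str | None = None
    threshold_A: float = 0.0
    temperature_K: float = 310.0
    n_active: int | None = None
    n_inactive: int | None = None
    delta_g_kcal_mol: float | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def classified(self) -> bool:
        return "label" in self.data.columns


def lbp_centroid(
    frame: Frame, trajectory: Trajectory, selection: ResidueSelection
) -> np.ndarray:
    """Unweighted mean position of the selected pocket atoms (Å)."""
    idx = resolve_selection(trajectory, selection)
    return frame.coordinates[idx].mean(axis=0)


def h12_distance(
    frame: Frame,
    trajectory: Trajectory,
    h12_selection: ResidueSelection,
    centroid: np.ndarray,
) -> float:
    """Maximum Euclidean distance from any selected H12 atom to the pocket
    centroid.

    With the default CA_ONLY selection each residue contributes its
    alpha-carbon, so this is the max over H12 residues of the
    residue-point-to-centroid distance.
    """
    idx = resolve_selection(trajectory, h12_selection)
    d = np.linalg.norm(frame.coordinates[idx] - np.asarray(centroid), axis=1)
    return float(d.max())


def relative_distance_series(
    trajectory: Trajectory,
    lbp: ResidueSelection,
    h12: ResidueSelection,
    temperature_K: float = 310.0,
) -> H12Profile:
    """Per-frame H12 distance minus the first frame's; frame 1 is exactly 0.

    The pocket centroid is recomputed per frame, so a rigid motion of an
    entire frame leaves its distance unchanged.
    """
    if trajectory.n_frames < 1:
        raise ValueError("trajectory has no frames")
    lbp_idx = resolve_selection(trajectory, lbp)
    h12_idx = resolve_selection(trajectory, h12)
    rows = []
    reference = None
    for frame in trajectory.frames:
        centroid = frame.coordinates[lbp_idx].mean(axis=0)
        dist = float(np.linalg.norm(
            frame.coordinates[h12_idx] - centroid, axis=1).max())
        if reference is None:
            reference = dist
        rows.append((frame.index, frame.time_ps, dist, dist - reference))
    data = pd.DataFrame(
        rows, columns=["frame", "time_ps", "h12_distance_A",
                       "relative_distance_A"]
    )
    data.loc[data.index[0], "relative_distance_A"] = 0.0
    return H12Profile(
        data=data,
        temperature_K=temperature_K,
        metadata={"lbp_selection": lbp.label, "h12_selection": h12.label,
                  "gas_constant_kcal_mol_K": GAS_CONSTANT_KCAL},
    )


def classify_forms(
    profile: H12Profile,
    initial_form: str,
    threshold_A: float = 0.0,
) -> H12Profile:
    """Label every frame active/inactive from its relative H12 distance.

    Frames farther out than the initial structure (relative distance above
    ``+threshold``) are inactive-like; frames closer in (below
    ``−threshold``) are active-like; boundary frames inherit the initial
    form.  Populations and, when both are non-empty, the activation free
    energy are stored on the returned profile.
    """
    if initial_form not in (ACTIVE, INACTIVE):
        raise ValueError("initial_form must be 'active' or 'inactive'")
    if threshold_A < 0:
        raise ValueError("threshold_A must be >= 0")
    rel = profile.data["relative_distance_A"].to_numpy()
    labels = np.where(
        rel > threshold_A, INACTIVE,
        np.where(rel < -threshold_A, ACTIVE, initial_form),
    )
    data = profile.data.copy()
    data["label"] = labels
    n_active = int(np.count_nonzero(labels == ACTIVE))
    n_inactive = int(np.count_nonzero(labels == INACTIVE))
    delta_g = None
    if n_active > 0 and n_inactive > 0:
        delta_g = activation_energy(n_active, n_inactive,
                                    profile.temperature_K)
    return H12Profile(
        data=data,
        initial_form=initial_form,
        threshold_A=threshold_A,
        temperature_K=profile.temperature_K,
        n_active=n_active,
        n_inactive=n_inactive,
        delta_g_kcal_mol=delta_g,
        metadata=dict(profile.metadata),
    )


def activation_energy(
    n_active: int, n_inactive: int, temperature_K: float = 310.0
) -> float:
    """ΔG = −RT·ln(N_active/N_inactive) in kcal/mol, R = 1.9872e-3.

    Both counts must be positive; for trajectories where one form is never
    visited, add a pseudo-count explicitly before calling (none is applied
    here by default).
    """
    if n_active <= 0 or n_inactive <= 0:
        raise ValueError(
            "both populations must be > 0 (the free energy of an unvisited "
            "form is undefined; consider adding an explicit pseudo-count)"
        )
    if temperature_K <= 0:
        raise ValueError("temperature_K must be positive")
    return -GAS_CONSTANT_KCAL * temperature_K * math.log(
        n_active / n_inactive
    )
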