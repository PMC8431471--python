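"""Helix-12 switch statistic: per-frame maximum distance from H12 to the
ligand-binding-pocket centroid, classified relative to the first frame,
with the population-based activation free energy
ΔG = −RT ln(N_active / N_inactive).
"""

import math

from ertraj import classify_forms, relative_distance_series
from ertraj.h12 import GAS_CONSTANT_KCAL
from ertraj.synthetic import (SyntheticSpec,
                              generate_receptor_ligand_trajectory,
                              h12_selection, lbp_selection)

f = 0.3  # planted probability of an outward (inactive-like) H12 frame
spec = SyntheticSpec(n_frames=2000, fraction_displaced=f, seed=7)
trajectory, truth = generate_receptor_ligand_trajectory(spec)

profile = relative_distance_series(trajectory, lbp_selection(),
                                   h12_selection(), temperature_K=310.0)
profile = classify_forms(profile, initial_form="active", threshold_A=0.0)

expected = -GAS_CONSTANT_KCAL * 310.0 * math.log((1 - f) / f)
print(f"N_active = {profile.n_active}, N_inactive = {profile.n_inactive}")
print(f"recovered inactive fraction: "
      f"{profile.n_inactive / trajectory.n_frames:.3f} (planted {f})")
print(f"activation free energy: {profile.delta_g_kcal_mol:.3f} kcal/mol "
      f"(closed form for f={f}: {expected:.3f})")
# A positive ΔG here would mean the active form is the minority; with 30%
# of frames displaced outward, the active (inward) form dominates and the
# population free energy is negative, close to −RT ln(0.7/0.3).
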