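"""Per-residue interaction persistence: the fraction of frames in which
each residue forms a hydrogen bond or hydrophobic contact with the
ligand — the "fraction of simulation time" bars of interaction diagrams.
"""

from ertraj import persistence_profile
from ertraj.synthetic import (SyntheticSpec,
                              generate_receptor_ligand_trajectory)

spec = SyntheticSpec(n_frames=1000, seed=7)
trajectory, truth = generate_receptor_ligand_trajectory(spec)

profile = persistence_profile(trajectory)
print(f"{'residue':<10}{'type':<14}{'fraction':>9}{'planted':>9}")
for row in profile.data.itertuples(index=False):
    label = f"{row.residue_name}{row.residue_number}"
    planted = truth.contact_fraction_planted.get(label, 0.0)
    print(f"{label:<10}{row.interaction_type:<14}"
          f"{row.fraction:>9.3f}{planted:>9.3f}")
# Recovered fractions sit within binomial sampling error of the planted
# persistences; a residue interacting in >60% of frames would be called a
# stable anchor of the binding mode.
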