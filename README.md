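# ertraj

Trajectory analysis of the nuclear-receptor helix-12 switch.

Estrogen receptor α (ERα) is a ligand-dependent transcription factor whose
C-terminal helix of the ligand-binding domain, helix 12 (H12), acts as a
molecular switch: agonists such as 17β-estradiol stabilize H12 packed
against the ligand-binding pocket (LBP, the transcriptionally active form),
while antagonists such as 4-hydroxytamoxifen push H12 outward (the inactive
form). `ertraj` implements, as a tested and reusable library, the analysis
chain used to tell these dynamic binding patterns apart in molecular
dynamics (MD) trajectories:

* **all-vs-all frame RMSD matrices** — minimized RMSD by Kabsch
  superposition (proper rotations only) over a configurable atom selection;
* **hierarchical conformational clustering** on the RMSD matrix, retention
  of major clusters (strictly more than `min_size` frames) and a **medoid
  representative frame** per cluster;
* **the H12 switch statistic** — per frame, the maximum distance from any
  H12 residue (Asp535–Leu549 by default) to the centroid of a 17-residue
  LBP set, expressed relative to the first frame, with frames classified
  active/inactive by sign and an activation free energy from the
  populations, ΔG = −RT ln(N_active/N_inactive), R = 1.9872×10⁻³
  kcal mol⁻¹ K⁻¹, T = 310 K;
* **a simplified MM-GB/SA-style energy evaluator** — seven components
  (Coulomb, covalent, H-bond, lipophilic, generalized-Born solvation,
  van der Waals, π–π packing) summed per species, with the binding free
  energy from the thermodynamic cycle
  ΔG_bind = E_complex − E_protein − E_ligand;
* **interaction persistence profiles** — per-residue fractions of frames
  with a hydrogen bond (donor–acceptor ≤ 3.5 Å, D–H···A ≥ 120° when
  hydrogens exist) or hydrophobic contact (C···C ≤ 4.5 Å) to the ligand;
* **a synthetic trajectory generator** that plants conformational basins,
  a two-state H12 switch and Bernoulli contacts with known ground truth,
  so every stage can be validated quantitatively.

Trajectories are read and written as multi-model PDB files. A thin CLI
(`ertraj synth|rmsd|cluster|h12|energy|interactions|run`) wraps the
library; `ertraj run --config pipeline.yaml` produces a complete,
seed-reproducible report bundle.

## Worked example

```python
from ertraj import classify_forms, relative_distance_series
from ertraj.synthetic import (SyntheticSpec, lbp_selection, h12_selection,
                              generate_receptor_ligand_trajectory)

spec = SyntheticSpec(n_frames=2000, fraction_displaced=0.3, seed=7)
trajectory, truth = generate_receptor_ligand_trajectory(spec)
profile = classify_forms(
    relative_distance_series(trajectory, lbp_selection(), h12_selection()),
    initial_form="active")
print(profile.n_active, profile.n_inactive, profile.delta_g_kcal_mol)
```

prints

```
1401 599 -0.5229...
```

i.e. 599 of 2000 frames (30.0%, planted 30%) have H12 displaced outward
and are classified inactive, and the population free energy −0.523
kcal/mol agrees with the closed form −RT ln(0.7/0.3) = −0.522 at 310 K.
The scripts in `examples/` walk through each capability the same way
(generation, RMSD + clustering, the H12 switch, binding energies,
interaction persistence, the full pipeline) and state what every printed
number means.

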