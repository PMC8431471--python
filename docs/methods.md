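# Methods

This note documents the models, conventions and design choices behind
`ertraj`, in the spirit of a package reference manual. Units are Å for
coordinates, ps for times and kcal/mol for energies throughout; every
frame index a user sees is 1-based.

## Superposition and RMSD matrices

The RMSD between two frames is minimized over all proper rigid motions:
both selections are centered, the optimal rotation is obtained from the
SVD of the 3×3 covariance matrix, and the determinant of the rotation is
constrained to +1 (the standard correction; mirror images are never
superposed onto each other, so a chiral structure and its reflection keep
a positive RMSD). The all-vs-all matrix computes the upper triangle only,
with batched 3×3 SVDs per row block, and mirrors it, so symmetry is exact
by construction. Mean-square deviations below 10⁻¹² of the coordinate
scale are snapped to exactly zero: for identical shapes the subtraction
of two large sums of squares leaves cancellation noise of order 10⁻⁷ Å
which would otherwise surface as spurious positive RMSDs.

The fitting selection defaults to the alpha-carbons of the whole
receptor; RMSD-matrix construction is O(n²) in frames, so the API takes a
`stride` and enforces a 5,000-frame cap by default (liftable explicitly;
the CLI logs the projected pair count before starting). Unit tests verify
agreement with an independent rotation-grid search refined by
Nelder–Mead, metric behaviour (symmetry, zero diagonal, triangle
inequality) and invariance of the matrix under a global rigid motion of
all frames.

## Hierarchical clustering and representatives

Clustering is agglomerative on the RMSD matrix (scipy linkage on the
condensed distances; `average` by default, `single`/`complete`
available). The tree is cut either at a requested number of clusters or
at a distance threshold; when neither is given the cut falls at 40% of
the largest RMSD in the matrix — a heuristic that lands in the gap
between within-basin and between-basin distances for well-separated
ensembles, and which users doing real analyses should override. Merge
ties are resolved by the linkage implementation's deterministic internal
order, so repeated runs on the same matrix always agree.

A "major" cluster is one with strictly more than `min_size` frames
(default 500), matching the convention of reporting only clusters with
more than 500 structures; smaller clusters stay in the assignment vector
but are excluded from reports. The representative of a cluster is its
medoid — the member frame minimizing the mean RMSD to all other members,
ties broken by the lowest frame index — because a report should cite a
real frame rather than a coordinate average, which may be unphysical.
An alternative convention averages coordinates over the cluster; the two
cannot both be honored and the medoid was chosen.

## The helix-12 switch statistic

Per frame: (1) the centroid of the LBP selection is the unweighted mean
of its atom positions (one alpha-carbon per residue by default; a
heavy-atom variant is available through the selection's atom mode);
(2) the H12 distance is the **maximum** over H12 residues of the
residue-point-to-centroid Euclidean distance — the maximum, not the mean,
so partial unwinding of the helix tip registers; (3) the relative
distance subtracts frame 1's value, making frame 1 exactly zero. Because
the centroid is recomputed within each frame, a rigid motion of an entire
frame leaves its distance unchanged; no cross-frame superposition is
involved.

Classification: relative distance above +`threshold` → inactive-like
(H12 farther out than initially), below −`threshold` → active-like,
inside the band → the declared initial form. The threshold defaults to
0 Å (a strict sign rule); the boundary tie rule is explicit so that zero
relative distances are reproducibly counted with the initial form. The
activation free energy is ΔG = −RT ln(N_active/N_inactive) with
R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹ and T defaulting to 310 K (the simulation
temperature convention for physiological studies); both counts must be
positive — no pseudo-count is applied silently, the error message points
the user at adding one deliberately. This is a population statistic over
classified frames, not a kinetic barrier.

## Simplified MM-GB/SA evaluator

The evaluator reproduces the *structure* of an MM-GB/SA calculation — a
seven-component sum per species and the cycle
ΔG_bind = E_complex − E_protein − E_ligand — with deliberately transparent
physics; it is not a force field and is never claimed to reproduce
production MM-GBSA numbers:

* Coulomb: Σ_{i<j} k·q_i q_j / (ε_r·r_ij), k = 332.0636 kcal·Å/(mol·e²),
  ε_in = 1; an optional distance-dependent dielectric (ε_r = r) is off by
  default.
* van der Waals: Lennard-Jones 12-6 with Lorentz–Berthelot combining
  rules (arithmetic σ, geometric ε).
* Solvation: the Still pairwise generalized-Born form over **ordered**
  pairs, −(k/2)(1/ε_in − 1/ε_out) Σ_i Σ_j q_i q_j / f_GB with
  f_GB = √(r² + a_i a_j exp(−r²/(4 a_i a_j))) and fixed per-atom Born
  radii; the i = j terms reproduce the Born ion energy
  −166.0318·(1 − 1/78.5)·q²/a exactly. ε_out = 78.5.
* Lipophilic: γ·SASA over hydrophobic-flagged atoms, γ = 0.0072
  kcal/(mol·Å²), probe 1.4 Å, 960 golden-spiral sphere points per atom
  (Shrake–Rupley-style rejection sampling); atomic radii are σ/2.
* Covalent, H-bond and π–π packing corrections: distance-thresholded pair
  counts times configurable weights, zero by default — the component-sum
  arithmetic is fully exercised without inventing parameters.

All atom pairs are treated as nonbonded (no exclusions, no cutoffs —
systems here are small). Consequences worth knowing: tightly spaced atoms
produce large positive absolute species energies, and with per-frame
Gaussian noise the receptor's absolute energy can spike when two trace
atoms wander close. The binding cycle is immune to this because the
complex and the separated species are evaluated at identical coordinates,
so all intra-species terms cancel exactly; ΔG_bind contains only
receptor–ligand cross terms plus the SASA nonadditivity. Tests pin the
Born ion and LJ-minimum closed forms, quadratic charge scaling, and
agreement with a naive double-loop re-summation to 10⁻⁸ kcal/mol.

## Interaction persistence

Hydrogen bonds are detected between polar heavy atoms (N, O) of ligand
and receptor at donor–acceptor distance ≤ 3.5 Å; when either partner has
attached hydrogens (same residue, within 1.25 Å) a D–H···A angle ≥ 120°
is also required, and with no hydrogens present the distance criterion
alone decides — the usual convention for heavy-atom-only models.
Hydrophobic contacts are carbon–carbon pairs within 4.5 Å. These are the
common literature thresholds, fully configurable; different MD packages'
interaction diagrams use their own (unpublished) criteria, so absolute
occupancies are comparable only within one criteria set. A residue–ligand
pair counts at most once per frame per interaction type; persistence is
frames-present / total frames, and zero-occupancy rows are suppressed.

## Synthetic data: what it emulates and what it does not

The generator builds a 64-residue alpha-carbon trace of an ideal helix
(rise 1.5 Å, 100° twist, radius 2.3 Å), numbered 486–549 so the terminal
segment 535–549 carries the canonical H12 numbering, plus a rigid
10-atom ring ligand (9 C + 1 O) placed outside the helix at pocket
height. Three planted signals drive the downstream analyses:

* **Basins** — a mobile segment (residues 523–534) sits at one of
  `n_basins` offsets of magnitude `basin_displacement_A` along random
  (seeded) directions, assigned to contiguous frame blocks sized by the
  basin weights; isotropic Gaussian noise of `noise_sigma_A` is added to
  every trace atom. This produces the block structure of a multi-basin
  RMSD matrix. Basins become unrecoverable as the displacement approaches
  the noise scale (a warning fires at ≤ 2σ).
* **The H12 switch** — when `fraction_displaced` > 0, each frame after
  the first is displaced (H12 translated outward by `h12_displacement_A`
  along the pocket-to-H12 axis) with that probability, else translated
  inward by the same amount; frame 1 stays at the reference. The inward
  placement of non-displaced frames makes the sign of the relative
  distance encode the planted state exactly, so recovery error is purely
  the Bernoulli sampling noise of the draws — which is what the binomial
  recovery guarantees quantify. With `fraction_displaced` = 0 H12 never
  moves.
* **Contacts** — designated residues carry a side-chain marker atom
  (carbon for hydrophobic, oxygen for hydrogen-bonding residues) placed
  inside the contact cutoff (3.5 Å C···C, 2.8 Å O···O) or at 9 Å,
  per frame, by independent Bernoulli draws at the planted persistence.
  Markers and the ligand carry no noise, so detection is exact and the
  ground-truth realized fractions are recovered identically.

Default conditions: 600 frames at 4.8 ps spacing, 3 equal-weight basins
8 Å apart, 0.5 Å noise — a separation-to-noise ratio comfortably above
the ≥ 6σ regime where clustering recovery is expected to be perfect —
and contact persistences spanning the stable (0.7) to transient (0.15)
range seen in interaction diagrams. The toy parameterization assigns
charges only to the planted polar pair (±0.4 e), making bound frames
strictly more favorable in ΔG_bind than unbound ones.

What passing tests on this generator shows: the statistics, clustering,
classification and bookkeeping are correct, and planted effect sizes are
recovered at the expected sampling error. What it does not show: anything
about force-field accuracy, solvent, kinetics, or real conformational
ensembles — there is no physics in the generator beyond geometry.

## Pipeline and reproducibility

The pipeline runs input → RMSD → clustering → H12 → energy →
interactions in fixed order; stages can be skipped, and a stage whose
input was skipped fails fast with the missing dependency named before any
computation. Configuration is strict YAML (unknown keys rejected with a
did-you-mean suggestion; all defaults resolved and echoed to the run
log). Every output file is stamped with a short hash of the scientific
parameters (the output directory is excluded from the hash) and the seed;
CSV floats are fixed-precision (4 decimals for Å, 2 for kcal/mol, the
usual print precision for these quantities), which is what makes re-runs
byte-identical.

Problem sizes used by the validation suite — 600-frame matrices for
clustering and metric checks, 2,000 frames for H12 population recovery,
1,000 frames for persistence recovery, ≤ 50-atom systems for the energy
oracle — were chosen so each recovery guarantee has comfortable
statistical power while the whole suite stays interactive.

## Known limitations

* PDB only (no DCD/XTC/mmCIF); insertion codes rejected; for alternate
  locations the highest-occupancy conformer is kept (first on tie).
* No bonded topology anywhere: the evaluator excludes nothing, hydrogen
  attachment is inferred by distance, and "covalent" is a counted term
  with zero default weight.
* The H12 statistic uses alpha-carbons as residue points by default; the
  choice between CA, side-chain or residue centroids changes absolute
  distances (not the relative-distance sign structure for rigid
  displacements).
* The activation free energy is a population ratio over one trajectory;
  it inherits all sampling limitations of that trajectory.
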