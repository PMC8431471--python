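"""End-to-end orchestration: input → RMSD matrix → clustering → H12
switch → binding energies → interaction persistence.

``run_pipeline`` executes the stages in that fixed order and writes one
report bundle into the output directory:

* ``rmsd_matrix.csv`` — all-vs-all matrix (heat-map ready),
* ``clusters.csv`` — major-cluster table (number, size, span, medoid),
* ``h12_profile.csv`` / ``h12_summary.json`` — per-frame switch series
  and the population-based activation free energy,
* ``energy_report.csv`` — per-representative binding-cycle energies,
* ``interactions.csv`` — per-residue interaction persistence,
* ``run_log.json`` — seed, versions, resolved parameters.

Every file is stamped with the configuration hash and seed, so a bundle
is reproducible byte-for-byte from its config.
"""

from __future__ import annotations

import csv
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd

from . import __version__
from .clustering import (ClusterSet, cluster_report, filter_major_clusters,
                         hierarchical_cluster)
from .config import ConfigError, PipelineConfig, validate_config
from .core import ResidueSelection, Trajectory
from .energy import (AtomParameters, BindingEnergyResult, EvaluatorOptions,
                     trajectory_energy_profile)
from .h12 import H12Profile, classify_forms, relative_distance_series
from .interactions import (HBondCriteria, InteractionCriteria,
                           InteractionProfile, persistence_profile,
                           write_profile)
from .pdbio import read_multimodel_pdb
from .rmsd import RMSDMatrix, export_matrix, pairwise_rmsd
from .synthetic import (SyntheticSpec, default_parameters, fit_selection,
                        generate_receptor_ligand_trajectory, h12_selection,
                        lbp_selection)

__all__ = ["PipelineResult", "run_pipeline", "load_parameters",
           "write_parameters"]

logger = logging.getLogger(__name__)

ENERGY_COLUMNS = (
    "Frame", "dG_Bind", "dG_Bind_Coulomb", "dG_Bind_vdW",
    "Ligand Energy", "Complex Energy", "Receptor Energy",
)


@dataclass
class PipelineResult:
    """In-memory handles to everything a run produced."""

    config: PipelineConfig
    config_hash: str
    output_dir: Path
    trajectory: Trajectory
    matrix: Optional[RMSDMatrix] = None
    clusters: Optional[ClusterSet] = None
    h12_profile: Optional[H12Profile] = None
    energies: list[BindingEnergyResult] = field(default_factory=list)
    interactions: Optional[InteractionProfile] = None
    ground_truth: Any = None


def load_parameters(path: str | Path) -> AtomParameters:
    """Atom-parameter CSV: serial, charge, sigma, epsilon, born_radius,
    hydrophobic (0/1), in topology order."""
    df = pd.read_csv(path, comment="#")
    return AtomParameters(
        charge=df["charge"].to_numpy(float),
        sigma=df["sigma"].to_numpy(float),
        epsilon=df["epsilon"].to_numpy(float),
        born_radius=df["born_radius"].to_numpy(float),
        hydrophobic=df["hydrophobic"].to_numpy(int).astype(bool),
    )


def write_parameters(params: AtomParameters, path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["serial", "charge", "sigma", "epsilon",
                         "born_radius", "hydrophobic"])
        for i in range(len(params)):
            writer.writerow([
                i + 1, f"{params.charge[i]:.4f}", f"{params.sigma[i]:.4f}",
                f"{params.epsilon[i]:.4f}", f"{params.born_radius[i]:.4f}",
                int(params.hydrophobic[i]),
            ])


def _stamp(path: Path, config_hash: str, seed: int) -> None:
    """Prepend a provenance comment naming the config hash and seed."""
    body = path.read_text()
    path.write_text(f"# config_hash={config_hash} seed={seed}\n{body}")


def _build_selections(config: PipelineConfig):
    sel = config.selections
    fit = sel.fit.build("fit") if sel.fit else fit_selection()
    lbp = sel.lbp.build("LBP") if sel.lbp else lbp_selection()
    h12 = sel.h12.build("H12") if sel.h12 else h12_selection()
    return fit, lbp, h12


def _require(value, stage: str, needed_by: str):
    if value is None:
        raise ConfigError([
            f"stage '{needed_by}' needs the output of skipped stage "
            f"'{stage}'; remove '{stage}' from skip"
        ])
    return value


def run_pipeline(config: PipelineConfig | str | Path | dict,
                 ) -> PipelineResult:
    """Run the full analysis described by a validated config (or a config
    file path / mapping, validated here)."""
    if not isinstance(config, PipelineConfig):
        config = validate_config(config)
    # fail early on impossible stage dependencies
    skip = set(config.skip)
    if "rmsd" in skip and "cluster" not in skip:
        raise ConfigError([
            "stage 'cluster' needs the output of skipped stage 'rmsd'; "
            "skip 'cluster' as well or run 'rmsd'"
        ])
    if "cluster" in skip and "energy" not in skip:
        raise ConfigError([
            "stage 'energy' needs representative frames from skipped "
            "stage 'cluster'; skip 'energy' as well or run 'cluster'"
        ])

    config_hash = config.config_hash()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    ground_truth = None
    if config.synthetic is not None:
        kwargs = {k: v for k, v in config.synthetic.model_dump().items()
                  if v is not None}
        if "hbond_residues" in kwargs:
            kwargs["hbond_residues"] = frozenset(kwargs["hbond_residues"])
        if "basin_weights" in kwargs:
            kwargs["basin_weights"] = tuple(kwargs["basin_weights"])
        spec = SyntheticSpec(seed=config.seed, **kwargs)
        trajectory, ground_truth = generate_receptor_ligand_trajectory(spec)
        params = default_parameters(trajectory)
        logger.info("generated synthetic trajectory: %d frames, %d atoms",
                    trajectory.n_frames, trajectory.n_atoms)
    else:
        trajectory = read_multimodel_pdb(config.trajectory)
        params = (load_parameters(config.parameters)
                  if config.parameters else None)
        logger.info("loaded %s: %d frames, %d atoms", config.trajectory,
                    trajectory.n_frames, trajectory.n_atoms)

    fit, lbp, h12 = _build_selections(config)
    result = PipelineResult(config=config, config_hash=config_hash,
                            output_dir=outdir, trajectory=trajectory,
                            ground_truth=ground_truth)

    if "rmsd" not in skip:
        n_after = (trajectory.n_frames + config.stride - 1) // config.stride
        logger.info("rmsd: %d frames after stride %d (%d pairs)",
                    n_after, config.stride, n_after * (n_after - 1) // 2)
        result.matrix = pairwise_rmsd(trajectory, fit, stride=config.stride,
                                      max_frames=config.max_frames)
        path = outdir / "rmsd_matrix.csv"
        export_matrix(result.matrix, path)
        _stamp(path, config_hash, config.seed)

    if "cluster" not in skip:
        matrix = _require(result.matrix, "rmsd", "cluster")
        cl = config.clustering
        clusters = hierarchical_cluster(matrix, linkage=cl.linkage,
                                        n_clusters=cl.n_clusters,
                                        cut_distance=cl.cut_distance)
        result.clusters = filter_major_clusters(clusters, cl.min_size)
        path = outdir / "clusters.csv"
        cluster_report(result.clusters, path)
        _stamp(path, config_hash, config.seed)

    if "h12" not in skip:
        profile = relative_distance_series(
            trajectory, lbp, h12, temperature_K=config.h12.temperature_K)
        result.h12_profile = classify_forms(
            profile, config.h12.initial_form, config.h12.threshold_A)
        _write_h12(result.h12_profile, outdir, config_hash, config.seed)

    if "energy" not in skip:
        clusters = _require(result.clusters, "cluster", "energy")
        reps = [c.representative_frame for c in clusters.retained]
        if not reps:
            warnings.warn(
                "no retained clusters; energy stage falls back to the "
                "representatives of all clusters", stacklevel=2)
            reps = [c.representative_frame for c in clusters.clusters]
        if params is None:
            raise ConfigError([
                "energy stage requires an atom-parameter CSV "
                "('parameters') for a real trajectory"
            ])
        e = config.energy
        options = EvaluatorOptions(
            dielectric_in=e.dielectric_in,
            dielectric_out=e.dielectric_out,
            distance_dependent_dielectric=e.distance_dependent_dielectric,
            surface_tension=e.surface_tension,
            probe_radius_A=e.probe_radius_A,
            n_sphere_points=e.n_sphere_points,
        )
        result.energies = trajectory_energy_profile(
            trajectory, params, sorted(reps), options)
        _write_energy(result.energies, outdir / "energy_report.csv",
                      config_hash, config.seed)

    if "interactions" not in skip:
        ic = config.interactions
        criteria = InteractionCriteria(
            hbond=HBondCriteria(ic.hbond_distance_A, ic.hbond_angle_min_deg),
            hydrophobic_cutoff_A=ic.hydrophobic_distance_A,
        )
        result.interactions = persistence_profile(trajectory, criteria)
        path = outdir / "interactions.csv"
        write_profile(result.interactions, path)
        _stamp(path, config_hash, config.seed)

    _write_run_log(config, config_hash, outdir)
    return result


def _write_h12(profile: H12Profile, outdir: Path, config_hash: str,
               seed: int) -> None:
    path = outdir / "h12_profile.csv"
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame", "time_ps", "h12_distance_A",
                         "relative_distance_A", "label"])
        for row in profile.data.itertuples(index=False):
            writer.writerow([
                int(row.frame), f"{row.time_ps:.1f}",
                f"{row.h12_distance_A:.4f}",
                f"{row.relative_distance_A:.4f}", row.label,
            ])
    _stamp(path, config_hash, seed)
    summary = {
        "config_hash": config_hash,
        "seed": seed,
        "N_active": profile.n_active,
        "N_inactive": profile.n_inactive,
        "initial_form": profile.initial_form,
        "threshold_A": profile.threshold_A,
        "temperature_K": profile.temperature_K,
        "gas_constant_kcal_mol_K": profile.metadata.get(
            "gas_constant_kcal_mol_K"),
        "delta_g_kcal_mol": (
            None if profile.delta_g_kcal_mol is None
            else round(profile.delta_g_kcal_mol, 6)),
    }
    (outdir / "h12_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n")


def _write_energy(energies: list[BindingEnergyResult], path: Path,
                  config_hash: str, seed: int) -> None:
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(ENERGY_COLUMNS)

        def _row(label, dg, dg_coul, dg_vdw, e_lig, e_cplx, e_rec):
            writer.writerow([
                label, f"{dg:.2f}", f"{dg_coul:.2f}", f"{dg_vdw:.2f}",
                f"{e_lig:.2f}", f"{e_cplx:.2f}", f"{e_rec:.2f}",
            ])

        for res in energies:
            d = res.delta_components
            _row(res.frame_index, res.binding.delta_g_bind, d.coulomb, d.vdw,
                 res.binding.e_ligand, res.binding.e_complex,
                 res.binding.e_protein)
        if energies:
            _row(
                "mean",
                float(np.mean([r.binding.delta_g_bind for r in energies])),
                float(np.mean([r.delta_components.coulomb
                               for r in energies])),
                float(np.mean([r.delta_components.vdw for r in energies])),
                float(np.mean([r.binding.e_ligand for r in energies])),
                float(np.mean([r.binding.e_complex for r in energies])),
                float(np.mean([r.binding.e_protein for r in energies])),
            )
    _stamp(path, config_hash, seed)


def _write_run_log(config: PipelineConfig, config_hash: str,
                   outdir: Path) -> None:
    import scipy

    log = {
        "config_hash": config_hash,
        "seed": config.seed,
        "versions": {
            "ertraj": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
        "parameters": config.model_dump(mode="json"),
    }
    (outdir / "run_log.json").write_text(
        json.dumps(log, indent=2, sort_keys=True) + "\n")
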