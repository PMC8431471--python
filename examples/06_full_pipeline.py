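"""Run the whole pipeline from a config mapping (the YAML file form is
identical) and list the report bundle it writes."""

from pathlib import Path

from ertraj import run_pipeline

result = run_pipeline({
    "synthetic": {"n_frames": 400, "fraction_displaced": 0.3},
    "clustering": {"n_clusters": 3, "min_size": 50},
    "output_dir": "pipeline_out",
    "seed": 11,
})

print(f"config hash: {result.config_hash}")
for path in sorted(Path(result.output_dir).iterdir()):
    print(f"  {path.name}: {path.stat().st_size} bytes")
print(f"clusters retained: {len(result.clusters.retained)}")
print(f"H12 populations: {result.h12_profile.n_active} active / "
      f"{result.h12_profile.n_inactive} inactive, "
      f"dG = {result.h12_profile.delta_g_kcal_mol:.3f} kcal/mol")
# Re-running with the same config and seed reproduces every file
# byte-for-byte; the config hash in each file ties outputs to parameters.
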