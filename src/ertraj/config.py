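"""Pipeline configuration: a typed YAML schema with strict key checking.

Unknown keys are rejected with a did-you-mean suggestion rather than
silently ignored, and all defaults are resolved at validation time so the
run log can echo the exact parameter set that produced an output bundle.
"""

from __future__ import annotations

import difflib
import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, model_validator

from .core import AtomMode, ResidueSelection

__all__ = [
    "ConfigError",
    "PipelineConfig",
    "SelectionConfig",
    "validate_config",
    "parse_residue_spec",
]

STAGES = ("rmsd", "cluster", "h12", "energy", "interactions")


class ConfigError(ValueError):
    """One or more configuration problems, aggregated before any
    computation starts."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid configuration:\n  - "
                         + "\n  - ".join(problems))


def parse_residue_spec(spec: str | list[int], chain: str = "A"
                       ) -> list[tuple[str, int]]:
    """Parse "535-549" or "490,492,494" (or an int list) into members."""
    if isinstance(spec, list):
        return [(chain, int(r)) for r in spec]
    members: list[tuple[str, int]] = []
    for part in str(spec).split(","):
        part = part.strip()
        if "-" in part:
            lo, hi = part.split("-", 1)
            members.extend((chain, r) for r in range(int(lo), int(hi) + 1))
        elif part:
            members.append((chain, int(part)))
    return members


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SelectionConfig(_StrictModel):
    chain: str = "A"
    residues: str | list[int]
    atom_mode: Literal["CA_ONLY", "HEAVY", "ALL"] = "CA_ONLY"

    def build(self, label: str) -> ResidueSelection:
        return ResidueSelection(
            label, parse_residue_spec(self.residues, self.chain),
            AtomMode(self.atom_mode),
        )


class SyntheticConfig(_StrictModel):
    n_frames: int = 600
    n_basins: int = 3
    basin_weights: Optional[list[float]] = None
    basin_displacement_A: float = 8.0
    noise_sigma_A: float = 0.5
    fraction_displaced: float = 0.3
    h12_displacement_A: float = 4.0
    contact_persistence: Optional[dict[str, float]] = None
    hbond_residues: Optional[list[str]] = None
    frame_interval_ps: float = 4.8


class SelectionsConfig(_StrictModel):
    fit: Optional[SelectionConfig] = None
    lbp: Optional[SelectionConfig] = None
    h12: Optional[SelectionConfig] = None
    # defaults (the synthetic scaffold's selections) are filled by the
    # pipeline when omitted


class ClusteringConfig(_StrictModel):
    linkage: Literal["single", "complete", "average"] = "average"
    n_clusters: Optional[int] = None
    cut_distance: Optional[float] = None
    min_size: int = 500


class H12Config(_StrictModel):
    initial_form: Literal["active", "inactive"] = "active"
    threshold_A: float = 0.0
    temperature_K: float = 310.0


class EnergyConfig(_StrictModel):
    dielectric_in: float = 1.0
    dielectric_out: float = 78.5
    distance_dependent_dielectric: bool = False
    surface_tension: float = 0.0072
    probe_radius_A: float = 1.4
    n_sphere_points: int = 960


class InteractionConfig(_StrictModel):
    hbond_distance_A: float = 3.5
    hbond_angle_min_deg: float = 120.0
    hydrophobic_distance_A: float = 4.5


class PipelineConfig(_StrictModel):
    """Full pipeline configuration; exactly one of ``trajectory`` /
    ``synthetic`` selects the input."""

    trajectory: Optional[str] = None
    parameters: Optional[str] = None  # atom-parameter CSV for energy stage
    synthetic: Optional[SyntheticConfig] = None
    selections: SelectionsConfig = SelectionsConfig()
    stride: int = 1
    max_frames: int = 5000
    clustering: ClusteringConfig = ClusteringConfig()
    h12: H12Config = H12Config()
    energy: EnergyConfig = EnergyConfig()
    interactions: InteractionConfig = InteractionConfig()
    skip: list[Literal["rmsd", "cluster", "h12", "energy", "interactions"]] \
        = []
    output_dir: str = "ertraj_out"
    seed: int = 0

    @model_validator(mode="after")
    def _one_input(self) -> "PipelineConfig":
        if (self.trajectory is None) == (self.synthetic is None):
            raise ValueError(
                "exactly one of 'trajectory' and 'synthetic' must be set"
            )
        return self

    def config_hash(self) -> str:
        """Short hash of the scientific parameters (the output directory
        does not affect results and is excluded)."""
        payload = self.model_dump(mode="json")
        payload.pop("output_dir", None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


def _known_keys(model: type[BaseModel]) -> list[str]:
    return list(model.model_fields)


def _format_errors(exc: ValidationError) -> list[str]:
    problems = []
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"]) or "<root>"
        msg = err["msg"]
        if err["type"] == "extra_forbidden":
            bad = str(err["loc"][-1])
            parent: type[BaseModel] = PipelineConfig
            for part in err["loc"][:-1]:
                ann = parent.model_fields[str(part)].annotation
                for cand in getattr(ann, "__args__", (ann,)):
                    if isinstance(cand, type) and issubclass(cand, BaseModel):
                        parent = cand
                        break
            close = difflib.get_close_matches(bad, _known_keys(parent), n=1)
            hint = f" (did you mean {close[0]!r}?)" if close else ""
            problems.append(f"{loc}: unknown key{hint}")
        else:
            problems.append(f"{loc}: {msg}")
    return problems


def validate_config(source: str | Path | dict) -> PipelineConfig:
    """Load and validate a YAML config file (or a pre-parsed mapping).

    Raises :class:`ConfigError` carrying every problem found, including
    unknown keys with suggestions.
    """
    if isinstance(source, (str, Path)):
        try:
            raw = yaml.safe_load(Path(source).read_text())
        except yaml.YAMLError as exc:
            raise ConfigError([f"not parseable as YAML: {exc}"]) from exc
    else:
        raw = source
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(["top level must be a mapping"])
    try:
        return PipelineConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigError(_format_errors(exc)) from exc
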