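"""Run configuration for the two-state comparison pipeline.

Defaults mirror the reference analysis conditions: equilibrated window
100–1000 (frame labels, i.e. ns), every tenth frame, core residues 1–407,
domain split at 305, PC1 excluded with 10 modes compared, tunnel probe
1.5 Å with 3.0 Å clustering and 0.6 Å grid spacing, RIN threshold 0.3
within 2 steps of residue 352, ±0.5 Å differential-RMSF and ±0.2 nm²
differential-SASA rules.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .synthetic import SyntheticSpec, spec_from_dict

__all__ = ["ComparisonConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    pass


@dataclass
class ComparisonConfig:
    # input: either a synthetic spec or per-state lists of multi-model PDBs;
    # states are ordered (oxy-like, deoxy-like) and differentials are
    # always state2 − state1 (deoxy − oxy)
    synthetic: SyntheticSpec = None
    ensemble_files: dict = None
    states: tuple = ("oxy", "deoxy")

    window: tuple = (100.0, 1000.0)
    stride: int = 10

    core_selection: str = "core"
    # rotation is fitted/measured on the rigid domain cores (loops and
    # tail excluded), the conventional choice for domain-motion analysis
    domain1_selection: str = "domain1_rigid"
    domain2_selection: str = "domain2_rigid"
    sasa_selection: str = "protein"
    rin_selection: str = "protein_core"  # contacts among core residues (tail excluded)
    tunnel_selection: str = None       # default: shell + gate for synthetic runs

    pca_exclude: tuple = (1,)
    pca_modes: int = 10
    pca_projection: tuple = (2, 3)

    sasa_probe: float = 1.4
    sasa_points: int = 960

    tunnel_probe: float = 1.5
    tunnel_cluster_threshold: float = 3.0
    tunnel_spacing: float = 0.6
    tunnel_max_per_frame: int = 5
    tunnel_seed_point: tuple = None    # explicit coordinate; or
    tunnel_seed_atoms: tuple = None    # atom index pair whose midpoint seeds

    rin_focal: int = 352
    rin_steps: int = 2
    rin_threshold: float = 0.3

    rmsf_threshold: float = 0.5        # Å
    dsasa_threshold: float = 0.2       # nm²

    rotation_test: str = "mannwhitney"

    outdir: str = "hemodyn_out"
    seed: int = 0

    def validate(self) -> None:
        if (self.synthetic is None) == (self.ensemble_files is None):
            raise ConfigError("provide exactly one of 'synthetic' or 'ensemble_files'")
        if len(self.states) != 2:
            raise ConfigError("exactly two states are required")
        if self.ensemble_files is not None:
            missing = [s for s in self.states if not self.ensemble_files.get(s)]
            if missing:
                raise ConfigError(f"no ensemble files for state(s) {missing}")
        for name in ("rmsf_threshold", "dsasa_threshold", "tunnel_probe",
                     "tunnel_cluster_threshold", "tunnel_spacing", "rin_threshold"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.stride < 1:
            raise ConfigError("stride must be >= 1")

    def to_dict(self) -> dict:
        data = asdict(self)
        return data


def load_config(path) -> ComparisonConfig:
    """Load a YAML or JSON config file."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if "synthetic" in data and data["synthetic"] is not None:
        data["synthetic"] = spec_from_dict(data["synthetic"])
    for key in ("states", "window", "pca_exclude", "pca_projection",
                "tunnel_seed_point", "tunnel_seed_atoms"):
        if key in data and data[key] is not None:
            data[key] = tuple(data[key])
    config = ComparisonConfig(**data)
    config.validate()
    return config
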