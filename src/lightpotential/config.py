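"""Pipeline configuration: one YAML document, one section per stage.

Each stage reads only its own section; the document round-trips through
YAML losslessly (plain scalars, lists and mappings only).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

#: default mapping from pipeline column names to PhotosynQ-style export
#: headers; overridable because the export dialect changes between
#: protocol versions.
DEFAULT_COLUMN_MAP = {
    "leaf_id": "ID",
    "device_id": "Device ID",
    "timestamp": "time",
    "par_amb": "Light Intensity (PAR)",
    "t_leaf": "Leaf Temperature",
    "t_ambient": "Ambient Temperature",
    "leaf_angle": "Leaf Angle",
    "spad": "SPAD",
    "lat": "Latitude",
    "lon": "Longitude",
}

REQUIRED_COLUMNS = ("leaf_id", "par_amb", "t_leaf", "spad")


@dataclass
class PipelineConfig:
    sim: dict = field(default_factory=dict)          # SimConfig overrides; {} = no simulation
    derive: dict = field(default_factory=dict)       # DeriveConfig overrides
    # default blacklist names the simulator's known-defective device id
    qc: dict = field(default_factory=lambda: {
        "device_blacklist": ["MSQ-99"], "rules": {}, "mode": "exclude"})
    cluster: dict = field(default_factory=lambda: {
        "responses": ["lef_amb"], "covariates": ["sqrt_par", "t_leaf"],
        "k_range": [1, 6], "families": None, "n_init": 4,
        "standardize": True, "seed": 0})
    mechanism: dict = field(default_factory=lambda: {"margin": 0.0})
    columns: dict = field(default_factory=lambda: dict(DEFAULT_COLUMN_MAP))
    input_path: str | None = None                    # PhotosynQ export; None = simulate
    outdir: str = "lightpotential_run"

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "PipelineConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        data = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise KeyError(f"unknown config sections: {sorted(unknown)}")
        return cls(**data)
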