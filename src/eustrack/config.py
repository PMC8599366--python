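"""Run configuration: one YAML file drives every pipeline stage.

The resolved configuration round-trips losslessly through YAML and carries a
content hash so that every run directory records exactly which settings
produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All tunables of the phantom-to-match pipeline."""

    probe_preset: str = "endoscopic_linear"
    # PSF
    elevation_slab_mm: float = 5.0
    lateral_sigma_mm: float | None = None
    dynamic_range_db: float = 60.0
    # Haar basis
    scales: list[int] = field(default_factory=lambda: [0, 1, 2, 3])
    base_support: int = 8
    stride_factor: float = 1.0
    match_size: int = 128
    n_templates: int = 8
    # pose grid
    n_offsets: int = 10
    offset_step_mm: float = 5.0
    rotations_deg: list[float] = field(default_factory=lambda: [0.0, 15.0, -15.0])
    plane_extent_mm: list[float] = field(default_factory=lambda: [100.0, 100.0])
    # phantom / scatterers
    scatterer_density_per_mm3: float = 5.0
    sphere_amplitude: float = 6.0
    median_window: int = 5
    # seeds
    phantom_seed: int = 0
    dictionary_seed: int = 12345
    target_seed: int = 777
    noise_seed: int = 778
    noise_sigma: float = 0.05
    # evaluation
    target_pose_index: int = 0
    n_markers: int = 4

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]
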