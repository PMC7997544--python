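"""Run configuration: a flat, validated parameter set with a stable hash.

Every stage parameter of the pipeline lives here so that a run is fully
reproducible from its config plus seed; unknown keys in a config file are
rejected rather than ignored, and the config hash is embedded in every
output artifact.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig"]

_CHANNEL_MODES = ("gag_anchored", "pol_anchored", "vpr_anchored", "none", "absent")


@dataclass
class RunConfig:
    """All pipeline stage parameters, flat.

    ``image_path = None`` means the run simulates its input field; the
    ``green_mode`` / ``red_mode`` keys pick the labeling construct rendered
    in each fluorescence channel (``absent`` drops the channel entirely).
    """

    # input / provenance
    image_path: str | None = None
    seed: int = 0

    # simulated field geometry and noise
    width_px: int = 512
    height_px: int = 512
    n_z: int = 5
    pixel_size_um: float = 0.108
    z_step_um: float = 0.25
    particle_density: float = 0.02
    background_level: float = 10.0
    read_noise_sd: float = 2.0
    mature_fraction: float = 0.9

    # labeling constructs
    reference_channel: str = "farred"
    green_mode: str = "gag_anchored"
    green_incorporation: float = 1.0
    red_mode: str = "absent"
    red_incorporation: float = 1.0
    dual_label_fraction: float | None = None

    # optics
    numerical_aperture: float = 1.4
    refractive_index: float = 1.515
    deconv_iterations: int = 15

    # detection
    diameter_px: int = 7
    separation_px: float = 7.0
    min_mass: float | None = None  # None -> Otsu threshold of candidate masses
    percentile: float = 64.0

    # colocalization
    threshold_um: float = 0.500
    one_to_one: bool = False
    edge_correction: bool = True
    n_shuffles: int = 0

    # infectivity
    gate_quantile: float = 0.999
    singlet_tolerance: float = 3.0
    dunn_correction: str = "holm"

    def __post_init__(self) -> None:
        for key in ("green_mode", "red_mode"):
            if getattr(self, key) not in _CHANNEL_MODES:
                raise ValueError(f"{key} must be one of {_CHANNEL_MODES}")
        if self.threshold_um <= 0:
            raise ValueError("threshold_um must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        """Load from a flat YAML/key-value file; unknown keys are an error."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError("config file must hold a flat key-value mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @property
    def hash(self) -> str:
        """Short stable digest over every parameter; any change changes it."""
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]
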