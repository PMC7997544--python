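"""Image and table I/O.

Images travel as multi-page TIFF with axes C,Z,Y,X plus a JSON sidecar
(`<path>.json`) carrying the physical calibration (``pixel_size_um``,
``z_step_um``) and channel names.  All table output is plain CSV with
positions in micrometres and intensities in photons.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["ImageField", "write_image", "read_image"]


@dataclass
class ImageField:
    """A multi-channel Z-stack with physical pixel calibration.

    data : float array shaped (C, Z, Y, X), photon counts.
    channels : channel names, one per leading-axis slice.
    pixel_size_um : lateral pixel pitch in micrometres.
    z_step_um : axial plane spacing in micrometres.
    """

    data: np.ndarray
    channels: list[str]
    pixel_size_um: float
    z_step_um: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"data must be (C, Z, Y, X); got rank {self.data.ndim}")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channels)} channel names for {self.data.shape[0]} channel planes"
            )
        if self.pixel_size_um <= 0 or self.z_step_um <= 0:
            raise ValueError("calibration must be positive")

    @property
    def n_z(self) -> int:
        return self.data.shape[1]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    @property
    def width_um(self) -> float:
        return self.data.shape[3] * self.pixel_size_um

    @property
    def height_um(self) -> float:
        return self.data.shape[2] * self.pixel_size_um

    def channel(self, name: str) -> np.ndarray:
        """Return the (Z, Y, X) stack for a named channel."""
        try:
            idx = self.channels.index(name)
        except ValueError:
            raise KeyError(f"no channel {name!r}; have {self.channels}") from None
        return self.data[idx]


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def write_image(field: ImageField, path: str | Path) -> Path:
    """Write an ImageField as CZYX TIFF plus a JSON calibration sidecar."""
    path = Path(path)
    tifffile.imwrite(
        path,
        field.data.astype(np.float32),
        photometric="minisblack",
        metadata={"axes": "CZYX"},
    )
    sidecar = {
        "pixel_size_um": field.pixel_size_um,
        "z_step_um": field.z_step_um,
        "channels": list(field.channels),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_image(path: str | Path) -> ImageField:
    """Read a TIFF written by :func:`write_image` (or compatible) back.

    Calibration comes from the JSON sidecar; a missing sidecar or a sidecar
    missing a required field raises a ValueError naming the field.
    """
    path = Path(path)
    sc_path = _sidecar_path(path)
    if not sc_path.exists():
        raise ValueError(f"missing calibration sidecar {sc_path.name} (need pixel_size_um)")
    sidecar = json.loads(sc_path.read_text())
    for key in ("pixel_size_um", "z_step_um", "channels"):
        if key not in sidecar:
            raise ValueError(f"calibration sidecar missing required field {key!r}")

    data = tifffile.imread(path)
    n_c = len(sidecar["channels"])
    if data.ndim == 2:
        data = data[None, None]
    elif data.ndim == 3:
        # one squeezed axis: disambiguate with the channel count
        if data.shape[0] == n_c:
            data = data[:, None]
        elif n_c == 1:
            data = data[None]
        else:
            raise ValueError(
                f"ambiguous 3-D axes {data.shape} for {n_c} channels; cannot resolve C vs Z"
            )
    elif data.ndim != 4:
        raise ValueError(f"unsupported TIFF rank {data.ndim}")
    if data.shape[0] != n_c:
        raise ValueError(f"TIFF has {data.shape[0]} channel planes but sidecar names {n_c}")

    return ImageField(
        data=np.asarray(data, dtype=np.float32),
        channels=list(sidecar["channels"]),
        pixel_size_um=float(sidecar["pixel_size_um"]),
        z_step_um=float(sidecar["z_step_um"]),
    )
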