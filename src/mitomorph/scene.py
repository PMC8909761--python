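"""Core in-memory containers shared across the analysis stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi


@dataclass
class CellScene2D:
    """A single-cell 2D fluorescence scene: the unit of radial analysis.

    ``intensity`` is the (masked) marker signal, ``nucleus_mask`` and
    ``cell_mask`` binary masks of the nucleus and the whole cell.  ``center``
    defaults to the centroid of the nucleus mask; an explicit override is
    allowed for scenes where the nucleus centroid is a poor centre.
    """

    intensity: np.ndarray
    nucleus_mask: np.ndarray
    cell_mask: np.ndarray
    pixel_size: float = 1.0  # µm per pixel
    center: tuple[float, float] | None = None  # (row, col), pixels

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.nucleus_mask = np.asarray(self.nucleus_mask, dtype=bool)
        self.cell_mask = np.asarray(self.cell_mask, dtype=bool)
        if self.intensity.ndim != 2:
            raise ValueError("intensity must be 2D")
        if self.intensity.shape != self.nucleus_mask.shape != self.cell_mask.shape:
            raise ValueError("intensity and masks must share one shape")
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be non-negative")
        if np.any(self.nucleus_mask & ~self.cell_mask):
            raise ValueError("nucleus_mask must be contained in cell_mask")
        if self.center is None:
            self.center = tuple(ndi.center_of_mass(self.nucleus_mask))
        r, c = self.center
        if not self.nucleus_mask[int(round(r)), int(round(c))]:
            raise ValueError("center must lie inside the nucleus mask")


@dataclass
class VolumeFrame:
    """One 3D frame of a volumetric acquisition."""

    intensity: np.ndarray  # (z, y, x)
    voxel_size: tuple[float, float, float]  # µm, (z, y, x)
    timestamp: float = 0.0  # s
    channel: str = "mito"
    extra_channels: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 3:
            raise ValueError("intensity must be 3D (z, y, x)")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be strictly positive on all axes")

    @property
    def voxel_volume(self) -> float:
        vz, vy, vx = self.voxel_size
        return vz * vy * vx


@dataclass
class VolumeSeries:
    """A 4D (t, z, y, x) acquisition with one or two channels."""

    channels: dict[str, np.ndarray]
    voxel_size: tuple[float, float, float]
    frame_interval: float  # s
    t0: float = 0.0

    def __post_init__(self) -> None:
        shapes = {a.shape for a in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError("all channels must share one (t,z,y,x) shape")

    @property
    def n_frames(self) -> int:
        return next(iter(self.channels.values())).shape[0]

    def timestamps(self) -> np.ndarray:
        return self.t0 + self.frame_interval * np.arange(self.n_frames)

    def frame(self, t: int, channel: str | None = None) -> VolumeFrame:
        if channel is None:
            channel = next(iter(self.channels))
        extra = {
            name: arr[t] for name, arr in self.channels.items() if name != channel
        }
        return VolumeFrame(
            intensity=self.channels[channel][t],
            voxel_size=self.voxel_size,
            timestamp=float(self.timestamps()[t]),
            channel=channel,
            extra_channels=extra,
        )
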