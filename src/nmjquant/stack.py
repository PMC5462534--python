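"""In-memory image containers.

All geometry is physical (micrometres); voxel indices are 0-based and
ordered ``(z, y, x)``. Confocal stacks are anisotropic — the axial step
(z) is typically coarser than the lateral pixel size — so every length,
volume and distance in this package is computed from ``voxel_size``,
never from raw voxel counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ConfocalStack", "SectionImage"]


@dataclass
class ConfocalStack:
    """A multichannel 3D fluorescence stack.

    Parameters
    ----------
    voxels
        Intensity array indexed ``(channel, z, y, x)``, non-negative.
    channel_names
        One name per channel, e.g. ``["AChR", "nerve", "DAPI"]``.
    voxel_size
        Physical voxel dimensions ``(z, y, x)`` in micrometres.
    provenance
        Free-text acquisition / generation metadata.
    """

    voxels: np.ndarray
    channel_names: list[str]
    voxel_size: tuple[float, float, float]
    provenance: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 4:
            raise ValueError(f"expected (channel, z, y, x) array, got ndim={self.voxels.ndim}")
        if self.voxels.shape[0] < 1:
            raise ValueError("stack needs at least one channel")
        if len(self.channel_names) != self.voxels.shape[0]:
            raise ValueError("channel_names length must match number of channels")
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size must be a positive (z, y, x) triple, got {self.voxel_size}")
        self.voxel_size = vs
        if self.voxels.size and float(self.voxels.min()) < 0:
            raise ValueError("intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        """Spatial shape ``(z, y, x)``."""
        return self.voxels.shape[1:]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in μm³."""
        return float(np.prod(self.voxel_size))

    def channel(self, name: str) -> np.ndarray:
        """Return one channel's 3D array by name."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"no channel named {name!r}; have {self.channel_names}") from None
        return self.voxels[idx]


@dataclass
class SectionImage:
    """A multichannel 2D transverse-section image, square pixels."""

    pixels: np.ndarray
    channel_names: list[str]
    pixel_size: float  # μm per pixel
    provenance: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3:
            raise ValueError(f"expected (channel, y, x) array, got ndim={self.pixels.ndim}")
        if len(self.channel_names) != self.pixels.shape[0]:
            raise ValueError("channel_names length must match number of channels")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.pixels.size and float(self.pixels.min()) < 0:
            raise ValueError("intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[1:]

    def channel(self, name: str) -> np.ndarray:
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"no channel named {name!r}; have {self.channel_names}") from None
        return self.pixels[idx]
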