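"""Core container for multichannel 3D microscopy volumes.

A :class:`VolumeStack` holds one or more named intensity channels on a common
(z, y, x) voxel grid together with the physical voxel sizes. It is the unit of
analysis throughout the package — one acquired (or synthesized) z-stack.

Conventions
-----------
* Arrays are indexed ``(z, y, x)``; ``y`` increases downward in the stored
  array, but all angles reported by the package use the standard image-plane
  convention (x to the right, y up, angles counterclockwise).
* Intensities are non-negative float32.
* ``voxel_xy`` is the lateral sampling in µm/pixel, ``voxel_z`` the axial
  layer spacing in µm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VolumeStack"]


@dataclass
class VolumeStack:
    """Named-channel 3D intensity volume with physical voxel sizes.

    Parameters
    ----------
    channels
        Mapping of channel name (e.g. ``"SHG"``, ``"THG"``) to a 3D
        ``(z, y, x)`` array of non-negative intensities. All channels must
        share one shape.
    voxel_xy
        Lateral voxel size in µm/pixel (> 0).
    voxel_z
        Axial layer spacing in µm (> 0).
    stack_id
        Identifier of the stack; used in reports.
    group
        Sample-group label ("" when ungrouped).
    """

    channels: dict[str, np.ndarray]
    voxel_xy: float
    voxel_z: float
    stack_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("VolumeStack requires at least one channel")
        if not (self.voxel_xy > 0 and self.voxel_z > 0):
            raise ValueError("voxel sizes must be positive")
        shapes = {name: np.asarray(a).shape for name, a in self.channels.items()}
        first = next(iter(shapes.values()))
        if len(first) != 3:
            raise ValueError(f"channels must be 3D (z, y, x); got shape {first}")
        bad = {n: s for n, s in shapes.items() if s != first}
        if bad:
            raise ValueError(
                f"channel dimension mismatch: {bad} vs expected {first}"
            )
        coerced = {}
        for name, arr in self.channels.items():
            a = np.asarray(arr, dtype=np.float32)
            if a.size and float(a.min()) < 0:
                raise ValueError(f"channel {name!r} contains negative intensities")
            coerced[name] = a
        self.channels = coerced

    @property
    def shape(self) -> tuple[int, int, int]:
        """(n_layers, height, width) of every channel."""
        return next(iter(self.channels.values())).shape

    @property
    def n_layers(self) -> int:
        return self.shape[0]

    def layer_z_um(self) -> np.ndarray:
        """Physical depth of each layer, µm from the first layer."""
        return np.arange(self.n_layers, dtype=float) * self.voxel_z

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"stack {self.stack_id!r} has no channel {name!r}; "
                f"available: {sorted(self.channels)}"
            ) from None
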