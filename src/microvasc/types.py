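"""Core image containers.

Axis convention: channel arrays are indexed ``[i, j, k]`` with axis 0 = x,
axis 1 = y, axis 2 = z, so array axis ``a`` pairs with ``spacing[a]`` and the
physical center of voxel ``(i, j, k)`` is ``(idx + 0.5) * spacing`` µm plus
the origin.  TIFF I/O transposes to the conventional (z, y, x) plane order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile

CHANNEL_ORDER = ("nuclei", "vessel", "sma")


@dataclass
class VolumetricImage:
    """Multi-channel 3D intensity grid with anisotropic voxel spacing (µm)."""

    channels: dict[str, np.ndarray]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("at least one channel required")
        shapes = {c.shape for c in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels disagree on shape: {shapes}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing components must be > 0")
        for name, arr in self.channels.items():
            if arr.ndim != 3:
                raise ValueError(f"channel {name!r} must be 3D")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"channel {name!r} has non-finite intensities")
            if np.any(arr < 0):
                raise ValueError(f"channel {name!r} has negative intensities")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def voxel_volume(self) -> float:
        """µm³ per voxel."""
        return float(np.prod(self.spacing))

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical (x, y, z) center coordinate arrays, each of full shape."""
        sp = self.spacing
        grids = np.meshgrid(
            *[(np.arange(n) + 0.5) * sp[a] + self.origin[a]
              for a, n in enumerate(self.shape)],
            indexing="ij",
        )
        return tuple(grids)

    def to_tiff(self, path) -> None:
        """Write channels as a (C, Z, Y, X) stack; spacing in metadata."""
        names = [n for n in CHANNEL_ORDER if n in self.channels]
        names += sorted(set(self.channels) - set(names))
        stack = np.stack(
            [np.transpose(self.channels[n], (2, 1, 0)) for n in names]
        ).astype(np.float32)
        meta = {"spacing_um_xyz": list(self.spacing),
                "origin_um_xyz": list(self.origin),
                "channel_names": names, "axes_order": "CZYX"}
        tifffile.imwrite(path, stack, metadata=meta)

    @classmethod
    def from_tiff(cls, path, spacing=None) -> "VolumetricImage":
        """Read a (C, Z, Y, X) stack; `spacing` overrides stored metadata."""
        with tifffile.TiffFile(path) as tf:
            stack = tf.asarray()
            meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
        names = meta.get("channel_names") or [f"ch{i}" for i in range(stack.shape[0])]
        sp = spacing or meta.get("spacing_um_xyz")
        if sp is None:
            raise ValueError("no spacing in metadata; pass spacing explicitly")
        channels = {
            n: np.ascontiguousarray(np.transpose(stack[i], (2, 1, 0)), dtype=np.float64)
            for i, n in enumerate(names)
        }
        origin = tuple(meta.get("origin_um_xyz", (0.0, 0.0, 0.0)))
        return cls(channels=channels, spacing=tuple(sp), origin=origin)


@dataclass
class TissueMask:
    """Tissue-vs-glass segmentation with the thresholds that produced it."""

    mask: np.ndarray
    thresholds_used: list[float] = field(default_factory=list)
    n_levels: int = 0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        th = [float(t) for t in self.thresholds_used]
        if any(b <= a for a, b in zip(th, th[1:])):
            raise ValueError("thresholds must be strictly increasing")
        self.thresholds_used = th

    @property
    def volume_voxels(self) -> int:
        return int(self.mask.sum())

    def volume_um3(self, spacing) -> float:
        return self.volume_voxels * float(np.prod(spacing))

    def to_tiff(self, path) -> None:
        tifffile.imwrite(
            path,
            (np.transpose(self.mask, (2, 1, 0)).astype(np.uint8) * 255),
            metadata={"thresholds": self.thresholds_used, "n_levels": self.n_levels},
        )

    def thresholds_to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"thresholds": self.thresholds_used, "n_levels": self.n_levels}, fh
            )
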