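"""Calibrated multi-channel image stacks and their on-disk format.

Pixels live in a 4-D float array indexed ``(channel, plane, y, x)``, where a
"plane" is a confocal z-slice for fixed-cell stacks or a time frame for
movies.  Coordinates are pixel-centered, origin at the top-left corner,
``(y, x)`` order, 0-based; mask bounding boxes are half-open.  Calibration
(µm per pixel, seconds per frame, µm per z-step) always travels with the
pixel data in a JSON sidecar so that no downstream step assumes an implicit
scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["ImageStack"]


@dataclass
class ImageStack:
    """A calibrated image stack.

    Parameters
    ----------
    pixels
        Array of shape ``(n_channels, n_planes, height, width)``.
    channel_names
        One name per channel, e.g. ``("dna", "reporter")``.
    pixel_size
        Lateral calibration in µm per pixel (> 0).
    frame_interval
        Seconds per frame for time series; ``None`` for z-stacks.
    slice_step
        µm per z-slice for z-stacks; ``None`` for time series.
    """

    pixels: np.ndarray
    channel_names: tuple[str, ...]
    pixel_size: float
    frame_interval: float | None = None
    slice_step: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 4:
            raise ValueError(
                f"pixels must be 4-D (channel, plane, y, x); got shape {self.pixels.shape}"
            )
        self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != self.pixels.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {self.pixels.shape[0]} channels"
            )
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_planes(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.pixels.shape

    def channel_index(self, channel: int | str) -> int:
        if isinstance(channel, str):
            try:
                return self.channel_names.index(channel)
            except ValueError:
                raise KeyError(
                    f"channel {channel!r} not in {self.channel_names}"
                ) from None
        if not 0 <= channel < len(self.channel_names):
            raise KeyError(f"channel index {channel} out of range")
        return int(channel)

    def channel(self, channel: int | str) -> np.ndarray:
        """Return the ``(plane, y, x)`` sub-array of one channel."""
        return self.pixels[self.channel_index(channel)]

    # -- persistence -----------------------------------------------------------

    def save(self, path: str | Path) -> Path:
        """Write a multi-page float32 TIFF plus a ``<path>.json`` sidecar."""
        path = Path(path)
        tifffile.imwrite(path, self.pixels.astype(np.float32), photometric="minisblack")
        sidecar = {
            "shape": list(self.pixels.shape),
            "axes": "CPYX",
            "channel_names": list(self.channel_names),
            "pixel_size_um": self.pixel_size,
            "frame_interval_s": self.frame_interval,
            "slice_step_um": self.slice_step,
            "meta": self.meta,
        }
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "ImageStack":
        path = Path(path)
        sidecar_path = Path(str(path) + ".json")
        if not sidecar_path.exists():
            raise FileNotFoundError(f"calibration sidecar missing: {sidecar_path}")
        sidecar = json.loads(sidecar_path.read_text())
        pixels = tifffile.imread(path).reshape(sidecar["shape"]).astype(float)
        return cls(
            pixels=pixels,
            channel_names=tuple(sidecar["channel_names"]),
            pixel_size=float(sidecar["pixel_size_um"]),
            frame_interval=sidecar.get("frame_interval_s"),
            slice_step=sidecar.get("slice_step_um"),
            meta=sidecar.get("meta", {}),
        )
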