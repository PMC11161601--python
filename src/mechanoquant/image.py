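"""Calibrated image containers and TIFF I/O.

All images carry a physical pixel size (µm/px). Coordinates are 0-based
(row, col) pixel indices; subpixel positions are real-valued (row, col).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile


@dataclass
class MultichannelImage:
    """A 2D multichannel image with named channels on a shared pixel grid.

    Parameters
    ----------
    channels : dict of str -> ndarray
        Per-channel 2D intensity grids, all the same shape, nonnegative.
    pixel_size_um : float
        Physical edge length of one pixel in micrometres.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("at least one channel is required")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        shapes = {np.asarray(a).shape for a in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels have mismatched shapes: {shapes}")
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        for name, arr in self.channels.items():
            if arr.ndim != 2:
                raise ValueError(f"channel {name!r} is not 2D")
            if np.any(arr < 0):
                raise ValueError(f"channel {name!r} has negative intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]

    def __contains__(self, name: str) -> bool:
        return name in self.channels

    def require(self, *names: str) -> None:
        missing = [n for n in names if n not in self.channels]
        if missing:
            raise KeyError(
                f"required channels {missing} not found; available: {sorted(self.channels)}"
            )

    def save(self, path) -> None:
        """Write one page per channel; channel name + pixel size in the page description."""
        with tifffile.TiffWriter(path) as tif:
            for name, arr in self.channels.items():
                desc = json.dumps({"channel": name, "pixel_size_um": self.pixel_size_um})
                tif.write(arr.astype(np.float32), description=desc)

    @classmethod
    def load(cls, path, channel_names=None, pixel_size_um=None) -> "MultichannelImage":
        """Read a multichannel TIFF written by :meth:`save`, or any paged TIFF
        given explicit ``channel_names`` and ``pixel_size_um``."""
        channels: dict[str, np.ndarray] = {}
        px = pixel_size_um
        with tifffile.TiffFile(path) as tif:
            for i, page in enumerate(tif.pages):
                name = None
                desc = page.tags.get("ImageDescription")
                if desc is not None:
                    try:
                        meta = json.loads(desc.value)
                        name = meta.get("channel")
                        px = px or meta.get("pixel_size_um")
                    except (json.JSONDecodeError, TypeError):
                        pass
                if channel_names is not None:
                    name = channel_names[i]
                if name is None:
                    name = f"ch{i}"
                channels[name] = page.asarray().astype(float)
        if px is None:
            raise ValueError("pixel_size_um not found in TIFF metadata; pass it explicitly")
        return cls(channels=channels, pixel_size_um=float(px))


@dataclass
class ImageStack:
    """A single-channel time-lapse: frames indexed along axis 0."""

    frames: np.ndarray  # (t, rows, cols)
    pixel_size_um: float
    frame_interval_min: float | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (t, rows, cols) array")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def save(self, path) -> None:
        with tifffile.TiffWriter(path) as tif:
            for t in range(self.n_frames):
                desc = json.dumps(
                    {
                        "frame": t,
                        "pixel_size_um": self.pixel_size_um,
                        "frame_interval_min": self.frame_interval_min,
                    }
                )
                tif.write(self.frames[t].astype(np.float32), description=desc)

    @classmethod
    def load(cls, path, pixel_size_um=None, frame_interval_min=None) -> "ImageStack":
        px, dt = pixel_size_um, frame_interval_min
        pages = []
        with tifffile.TiffFile(path) as tif:
            for page in tif.pages:
                desc = page.tags.get("ImageDescription")
                if desc is not None:
                    try:
                        meta = json.loads(desc.value)
                        px = px or meta.get("pixel_size_um")
                        dt = dt or meta.get("frame_interval_min")
                    except (json.JSONDecodeError, TypeError):
                        pass
                pages.append(page.asarray().astype(float))
        if px is None:
            raise ValueError("pixel_size_um not found in TIFF metadata; pass it explicitly")
        return cls(frames=np.stack(pages), pixel_size_um=float(px), frame_interval_min=dt)
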