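"""In-memory image containers.

The screen acquires one 2-D optical section per field: a DAPI plane for
nuclear segmentation plus up to two FISH planes (pseudocolored red/green in
the original screen).  All coordinates reported downstream are micrometres in
the image frame, origin at the top-left pixel centre, x along columns and y
along rows; pixel indices are 0-based.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np


class Channel(str, Enum):
    DAPI = "DAPI"
    FISH_A = "FISH_A"
    FISH_B = "FISH_B"
    MARKER = "marker"


@dataclass(frozen=True)
class ImagePlane:
    """A single-channel 2-D intensity raster with physical pixel size."""

    raster: np.ndarray
    channel: Channel
    pixel_size_um: float

    def __post_init__(self) -> None:
        r = np.asarray(self.raster)
        if r.ndim != 2:
            raise ValueError(f"raster must be 2-D, got shape {r.shape}")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        object.__setattr__(self, "raster", r)
        object.__setattr__(self, "channel", Channel(self.channel))

    @property
    def shape(self) -> tuple[int, int]:
        return self.raster.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class LabelMask:
    """Integer nucleus-label raster: 0 = background, k > 0 = nucleus k.

    Labels are positive, contiguous (1..n) and sorted; connectivity of each
    label's pixel set is fixed by the segmentation configuration.
    """

    raster: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        r = np.asarray(self.raster)
        if r.ndim != 2:
            raise ValueError("label raster must be 2-D")
        if not np.issubdtype(r.dtype, np.integer):
            raise ValueError("label raster must be integer")
        object.__setattr__(self, "raster", r)

    @property
    def labels(self) -> np.ndarray:
        labs = np.unique(self.raster)
        return labs[labs > 0]

    @property
    def n_labels(self) -> int:
        return int(self.labels.size)
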