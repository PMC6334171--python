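"""Shared raster containers for two-channel fluorescence micrographs.

A field is a pair of co-registered channel rasters (DAPI, RedDot1) in
detector counts, plus the pixel size.  Compartments are described by a
label raster with the fixed code scheme used throughout the package:
0 background, 1 nucleus, 2 organellar DNA, 3 host nucleus (excluded
from all quantitation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

CHANNELS = ("DAPI", "RedDot1")

LABEL_BACKGROUND = 0
LABEL_NUCLEUS = 1
LABEL_ORGANELLE = 2
LABEL_HOST = 3
VALID_LABELS = frozenset((LABEL_BACKGROUND, LABEL_NUCLEUS, LABEL_ORGANELLE, LABEL_HOST))


@dataclass
class FieldImage:
    """Two-channel widefield micrograph (counts) with pixel size in um/px."""

    dapi: np.ndarray
    reddot: np.ndarray
    pixel_size: float = 0.1
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dapi = np.asarray(self.dapi, dtype=float)
        self.reddot = np.asarray(self.reddot, dtype=float)
        if self.dapi.ndim != 2 or self.reddot.ndim != 2:
            raise ValueError("channel rasters must be 2-D")
        if self.dapi.shape != self.reddot.shape:
            raise ValueError(
                f"channel shapes differ: DAPI {self.dapi.shape} vs RedDot1 {self.reddot.shape}"
            )
        if np.any(self.dapi < 0) or np.any(self.reddot < 0):
            raise ValueError("channel counts must be nonnegative")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.dapi.shape

    @property
    def channels(self) -> np.ndarray:
        """Stack of channels, axis 0 ordered as :data:`CHANNELS`."""
        return np.stack([self.dapi, self.reddot])


def validate_labels(labels: np.ndarray, name: str = "labels") -> np.ndarray:
    """Check a compartment label raster and return it as uint8.

    Rejects non-integer rasters and codes outside {0, 1, 2, 3}.
    """
    labels = np.asarray(labels)
    if labels.ndim != 2:
        raise ValueError(f"{name}: label raster must be 2-D")
    if not np.issubdtype(labels.dtype, np.integer):
        raise ValueError(f"{name}: label raster must have an integer dtype")
    codes = set(np.unique(labels).tolist())
    bad = codes - VALID_LABELS
    if bad:
        raise ValueError(f"{name}: unknown label codes {sorted(bad)} (allowed 0,1,2,3)")
    return labels.astype(np.uint8)
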