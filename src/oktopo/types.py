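"""Core data containers shared across the package.

A corneal topography is an RGB raster with a physical scale: the Tomey-style
exports this package targets use 50 px per millimetre, so geometry computed
in pixels converts to millimetres by a single division.  Region masks are
binary rasters for one of the two medically relevant zones — the pupil and
the orthokeratology treatment zone — which may overlap, hence masks are
multi-label rather than a partition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

PUPIL = "pupil"
TREATMENT_ZONE = "treatment_zone"
ROLES = (PUPIL, TREATMENT_ZONE)

#: default physical scale of the topography exports: 1 mm = 50 px
DEFAULT_PX_PER_MM = 50.0


@dataclass
class TopographyImage:
    """An RGB corneal topography with its pixel-to-millimetre scale."""

    pixels: np.ndarray  # H×W×3, uint8
    px_per_mm: float = DEFAULT_PX_PER_MM

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"expected H×W×3 pixels, got shape {self.pixels.shape}")
        h, w = self.pixels.shape[:2]
        if h < 32 or w < 32:
            raise ValueError(f"image too small: {h}×{w} (minimum 32×32)")
        if not self.px_per_mm > 0:
            raise ValueError("px_per_mm must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class RegionMask:
    """A binary mask (values 0/1) for one region role."""

    pixels: np.ndarray  # H×W, {0,1}
    role: str = PUPIL

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected H×W mask, got shape {self.pixels.shape}")
        vals = np.unique(self.pixels)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask values must be in {0, 1}")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")
        self.pixels = self.pixels.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def area(self) -> int:
        return int(self.pixels.sum())


def as_mask_array(mask) -> np.ndarray:
    """Accept a RegionMask or bare array; return a uint8 {0,1} H×W array."""
    m = mask.pixels if isinstance(mask, RegionMask) else np.asarray(mask)
    if m.ndim != 2:
        raise ValueError(f"expected 2-D mask, got shape {m.shape}")
    return (m > 0).astype(np.uint8)


def as_image_array(image) -> np.ndarray:
    """Accept a TopographyImage or bare H×W×3 array; return uint8 pixels."""
    px = image.pixels if isinstance(image, TopographyImage) else np.asarray(image)
    if px.ndim != 3 or px.shape[2] != 3:
        raise ValueError(f"expected H×W×3 image, got shape {px.shape}")
    return px.astype(np.uint8)
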