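"""Medical indicators computed from binary region masks.

Given the pupil and treatment-zone masks of one topography the pipeline
derives two numbers:

* **decentration** — the Euclidean distance between the region centers,
  where each center is the midpoint of the axis-aligned rectangle
  circumscribing the (denoised) region; converted to millimetres by the
  image scale (default 1 mm = 50 px).
* **EDCR** (effective defocusing contact range) — the fraction of the pupil
  boundary in contact with the defocus zone.  The defocus zone is the pupil
  minus its intersection with the treatment zone; boundaries are detected
  with the four-neighborhood rule (a positive pixel is boundary iff an
  up/down/left/right neighbour is zero or off-image); the effective contact
  value ECV counts pupil-boundary pixels that are simultaneously
  defocus-zone boundary pixels, and EDCR = ECV / C with C the pupil
  boundary length.

Coordinate convention: x = column, y = row, origin at the top-left pixel,
indices from 0; centers are real-valued.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .types import DEFAULT_PX_PER_MM, PUPIL, TREATMENT_ZONE, RegionMask, as_mask_array

__all__ = [
    "UngradableRegionError",
    "RegionGeometry",
    "IndicatorSet",
    "largest_component",
    "region_center",
    "decentration",
    "defocus_zone",
    "boundary_4n",
    "edcr",
    "compute_indicators",
]


class UngradableRegionError(ValueError):
    """A region required for grading is empty (nothing to measure)."""

    def __init__(self, region: str, message: str | None = None):
        self.region = region
        super().__init__(message or f"ungradable: region {region!r} is empty")


@dataclass
class RegionGeometry:
    """Boundary, circumscribed rectangle and its center for one region."""

    contour: np.ndarray  # (n, 2) boundary pixel coordinates as (x, y) rows
    bbox: tuple[int, int, int, int]  # (x_min, y_min, x_max, y_max), inclusive
    center_px: tuple[float, float]  # (x, y) = bbox midpoint


@dataclass
class IndicatorSet:
    """Decentration and EDCR plus the intermediate counts behind EDCR."""

    decentration_px: float
    decentration_mm: float
    edcr: float
    ecv_px: int | None = None
    pupil_boundary_len_px: int | None = None
    px_per_mm: float = DEFAULT_PX_PER_MM

    def __post_init__(self) -> None:
        if self.decentration_px < 0 or self.decentration_mm < 0:
            raise ValueError("decentration must be nonnegative")
        if not -1e-9 <= self.edcr <= 1 + 1e-9:
            raise ValueError(f"edcr {self.edcr} outside [0, 1]")
        self.edcr = float(min(max(self.edcr, 0.0), 1.0))

    def to_dict(self) -> dict:
        return {
            "decentration_px": self.decentration_px,
            "decentration_mm": self.decentration_mm,
            "edcr": self.edcr,
            "ecv_px": self.ecv_px,
            "pupil_boundary_len_px": self.pupil_boundary_len_px,
            "px_per_mm": self.px_per_mm,
        }


_STRUCT_4 = ndimage.generate_binary_structure(2, 1)
_STRUCT_8 = ndimage.generate_binary_structure(2, 2)


def largest_component(mask, connectivity: int = 8):
    """Keep only the largest connected component (segmentation denoising).

    Smaller blobs are treated as segmentation noise and zeroed.  Ties on
    area are broken deterministically toward the component containing the
    first positive pixel in row-major scan order.  An empty mask is returned
    unchanged.
    """
    role = mask.role if isinstance(mask, RegionMask) else None
    m = as_mask_array(mask)
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    if m.sum() == 0:
        return mask if isinstance(mask, RegionMask) else m
    labels, n = ndimage.label(m, structure=_STRUCT_4 if connectivity == 4 else _STRUCT_8)
    if n == 1:
        return mask if isinstance(mask, RegionMask) else m
    sizes = np.bincount(labels.ravel())[1:]
    best = np.flatnonzero(sizes == sizes.max()) + 1
    if len(best) > 1:
        # first positive pixel in scan order among tied components
        flat = labels.ravel()
        pos = np.flatnonzero(np.isin(flat, best))
        keep = flat[pos[0]]
    else:
        keep = best[0]
    out = (labels == keep).astype(np.uint8)
    return RegionMask(out, role=role) if role is not None else out


def boundary_4n(mask) -> np.ndarray:
    """Four-neighborhood boundary of a binary mask, as a boolean H×W array.

    A positive pixel is boundary iff at least one of its 4-neighbours is
    zero or lies outside the image (off-image neighbours count as zero, so
    the image border of a filled mask is boundary).
    """
    m = as_mask_array(mask).astype(bool)
    padded = np.pad(m, 1, constant_values=False)
    interior = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    return m & ~interior


def region_center(mask) -> RegionGeometry:
    """Locate a region's center via its circumscribed rectangle.

    The outer boundary is detected, the axis-aligned bounding rectangle of
    the region is taken, and its midpoint is the center (real-valued).
    """
    m = as_mask_array(mask)
    ys, xs = np.nonzero(m)
    if len(ys) == 0:
        role = mask.role if isinstance(mask, RegionMask) else "region"
        raise UngradableRegionError(role)
    x_min, x_max = int(xs.min()), int(xs.max())
    y_min, y_max = int(ys.min()), int(ys.max())
    b = boundary_4n(m)
    by, bx = np.nonzero(b)
    contour = np.column_stack([bx, by])
    return RegionGeometry(
        contour=contour,
        bbox=(x_min, y_min, x_max, y_max),
        center_px=((x_min + x_max) / 2.0, (y_min + y_max) / 2.0),
    )


def decentration(
    pupil_geom: RegionGeometry,
    tz_geom: RegionGeometry,
    px_per_mm: float = DEFAULT_PX_PER_MM,
) -> tuple[float, float]:
    """Euclidean center distance in px and mm (default scale 1 mm = 50 px)."""
    if px_per_mm <= 0:
        raise ValueError("px_per_mm must be positive")
    (x1, y1), (x2, y2) = pupil_geom.center_px, tz_geom.center_px
    d_px = float(np.hypot(x1 - x2, y1 - y2))
    return d_px, d_px / px_per_mm


def defocus_zone(pupil, tz):
    """Defocus zone = pupil minus (pupil ∩ treatment zone), binary {0,1}."""
    p = as_mask_array(pupil)
    t = as_mask_array(tz)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pupil {p.shape} vs treatment zone {t.shape}")
    return (p & ~(p & t)).astype(np.uint8)


def edcr(pupil, tz) -> IndicatorSet:
    """EDCR = ECV / C on binary masks (decentration fields left at 0).

    C is the pupil's four-neighborhood boundary length; ECV counts pupil
    boundary pixels shared with the boundary of the defocus zone.
    """
    p = as_mask_array(pupil)
    t = as_mask_array(tz)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pupil {p.shape} vs treatment zone {t.shape}")
    pb = boundary_4n(p)
    c = int(pb.sum())
    if c == 0:
        raise UngradableRegionError(PUPIL, "ungradable: pupil mask is empty")
    dz = defocus_zone(p, t)
    db = boundary_4n(dz)
    ecv = int(np.count_nonzero(pb & db))
    return IndicatorSet(
        decentration_px=0.0,
        decentration_mm=0.0,
        edcr=ecv / c,
        ecv_px=ecv,
        pupil_boundary_len_px=c,
    )


def compute_indicators(pupil, tz, px_per_mm: float = DEFAULT_PX_PER_MM) -> IndicatorSet:
    """Full indicator computation from raw (possibly noisy) masks.

    Each mask is denoised to its largest connected component, centers are
    located via circumscribed rectangles, and decentration and EDCR are
    assembled into one IndicatorSet.  Raises UngradableRegionError naming
    the offending region if either mask is empty after denoising.
    """
    p = as_mask_array(pupil)
    t = as_mask_array(tz)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pupil {p.shape} vs treatment zone {t.shape}")
    p = largest_component(p)
    t = largest_component(t)
    if p.sum() == 0:
        raise UngradableRegionError(PUPIL)
    if t.sum() == 0:
        raise UngradableRegionError(TREATMENT_ZONE)
    pg = region_center(p)
    tg = region_center(t)
    d_px, d_mm = decentration(pg, tg, px_per_mm)
    frag = edcr(p, t)
    return IndicatorSet(
        decentration_px=d_px,
        decentration_mm=d_mm,
        edcr=frag.edcr,
        ecv_px=frag.ecv_px,
        pupil_boundary_len_px=frag.pupil_boundary_len_px,
        px_per_mm=px_per_mm,
    )
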