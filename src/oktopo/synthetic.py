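"""Synthetic corneal-topography generator with exact ground truth.

Clinical tangential-map exports are not publicly available, so this module
renders topography-like images whose geometry is known by construction: a
dark near-circular pupil, a distinctly coloured treatment-zone disk, an
annular "steepened" defocus ring hugging the treatment zone, a smooth
background colour gradient and additive Gaussian noise.  Because both disks
are rasterised from analytic circles, the ground-truth masks, decentration,
EDCR and the resulting class label are exact, which makes every downstream
stage testable offline.

The renderer is deliberately not photo-realistic (no Placido rings, no
dioptre-faithful colour code): the downstream geometry consumes masks, not
colours, and the networks only need learnable contrast.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .classify import TopoClass, classify
from .indicators import IndicatorSet
from .types import DEFAULT_PX_PER_MM, PUPIL, TREATMENT_ZONE, RegionMask, TopographyImage

__all__ = [
    "CaseParams",
    "SyntheticCase",
    "ParamRanges",
    "analytic_edcr",
    "generate_case",
    "generate_dataset",
]


@dataclass
class CaseParams:
    """Full geometric and photometric description of one synthetic case."""

    image_size_px: tuple[int, int] = (320, 320)  # (height, width)
    px_per_mm: float = DEFAULT_PX_PER_MM
    pupil_center_px: tuple[float, float] = (160.0, 160.0)  # (x, y)
    pupil_radius_px: float = 55.0
    tz_center_px: tuple[float, float] = (160.0, 160.0)
    tz_radius_px: float = 80.0
    ring_width_px: float = 12.0
    noise_sd: float = 6.0
    background_seed: int = 0
    rng_seed: int = 0

    def validate(self) -> None:
        h, w = self.image_size_px
        if h < 32 or w < 32:
            raise ValueError("image must be at least 32×32")
        if self.px_per_mm <= 0:
            raise ValueError("px_per_mm must be positive")
        if self.pupil_radius_px <= 0 or self.tz_radius_px <= 0:
            raise ValueError("radii must be positive")
        if self.ring_width_px < 0 or self.noise_sd < 0:
            raise ValueError("ring_width_px and noise_sd must be nonnegative")
        for name, (cx, cy), r in (
            ("pupil", self.pupil_center_px, self.pupil_radius_px),
            ("treatment zone", self.tz_center_px, self.tz_radius_px),
        ):
            if cx - r < 0 or cy - r < 0 or cx + r > w - 1 or cy + r > h - 1:
                raise ValueError(
                    f"{name} disk (center ({cx:.1f}, {cy:.1f}), radius {r:.1f}) "
                    f"extends outside the {h}×{w} image"
                )


@dataclass
class SyntheticCase:
    image: TopographyImage
    pupil_mask: RegionMask
    tz_mask: RegionMask
    true_indicators: IndicatorSet
    true_class: TopoClass
    params: CaseParams


def analytic_edcr(
    pupil_center: tuple[float, float],
    pupil_radius: float,
    tz_center: tuple[float, float],
    tz_radius: float,
) -> float:
    """Closed-form EDCR for ideal circles.

    Returns the fraction of the pupil circle's circumference lying outside
    the treatment-zone disk.  When the circles intersect, the pupil arc
    inside the disk subtends 2·arccos((d² + r_p² − r_t²) / (2·d·r_p)) by the
    law of cosines on the center distance d, so the outside fraction is
    1 − arccos(·)/π.  Containment and tangency degenerate cases resolve by
    radius comparison.
    """
    if pupil_radius <= 0 or tz_radius <= 0:
        raise ValueError("radii must be positive")
    d = math.hypot(pupil_center[0] - tz_center[0], pupil_center[1] - tz_center[1])
    if d >= pupil_radius + tz_radius:
        return 1.0  # disjoint (or externally tangent): no contact with TZ
    if d + pupil_radius <= tz_radius:
        return 0.0  # pupil boundary entirely inside the TZ disk
    if d + tz_radius <= pupil_radius:
        return 1.0  # TZ disk strictly interior: boundary untouched
    cos_half = (d * d + pupil_radius**2 - tz_radius**2) / (2.0 * d * pupil_radius)
    half_angle = math.acos(min(1.0, max(-1.0, cos_half)))
    return 1.0 - half_angle / math.pi


# ---------------------------------------------------------------------------
# rendering

# colour families loosely following tangential-map conventions: warm
# mid-power background, cool (flattened) treatment zone, hot (steepened)
# defocus ring, near-black pupil
_BG_COLORS = np.array([[190, 170, 90], [170, 200, 110], [210, 160, 100], [180, 190, 130]])
_TZ_COLORS = np.array([[60, 130, 210], [70, 170, 190], [50, 110, 190], [90, 180, 220]])
_RING_COLORS = np.array([[220, 60, 40], [230, 100, 40], [200, 50, 60], [235, 140, 50]])


def _disk(h: int, w: int, center: tuple[float, float], radius: float) -> np.ndarray:
    cx, cy = center
    yy, xx = np.mgrid[0:h, 0:w]
    return ((xx - cx) ** 2 + (yy - cy) ** 2) <= radius * radius


def generate_case(params: CaseParams) -> SyntheticCase:
    """Render one case; fully reproducible from the two seeds in ``params``.

    Layer order matters clinically: the treatment zone is painted over the
    background and ring, and the pupil — "the circle of black pixels" — is
    drawn last because it overlaps the treatment zone.  Ground-truth masks
    are the exact rasterised disks (multi-label: they may overlap); the
    true indicators come from the analytic circle geometry, and the class
    from the grading rules applied to them.
    """
    params.validate()
    h, w = params.image_size_px
    bg_rng = np.random.default_rng(params.background_seed)
    noise_rng = np.random.default_rng(params.rng_seed)

    # background: linear gradient between two palette colours along a
    # random direction
    c0 = _BG_COLORS[bg_rng.integers(len(_BG_COLORS))].astype(np.float32)
    c1 = _BG_COLORS[bg_rng.integers(len(_BG_COLORS))].astype(np.float32) * 0.7
    theta = bg_rng.uniform(0, 2 * np.pi)
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float32)
    t = (xx * np.cos(theta) + yy * np.sin(theta))
    t = (t - t.min()) / max(float(np.ptp(t)), 1.0)
    img = c0[None, None, :] * (1 - t[..., None]) + c1[None, None, :] * t[..., None]

    # defocus ring: annulus of contrasting colour around the treatment zone
    if params.ring_width_px > 0:
        ring_outer = _disk(h, w, params.tz_center_px,
                           params.tz_radius_px + params.ring_width_px)
        tz_disk = _disk(h, w, params.tz_center_px, params.tz_radius_px)
        ring = ring_outer & ~tz_disk
        ring_color = _RING_COLORS[bg_rng.integers(len(_RING_COLORS))].astype(np.float32)
        img[ring] = ring_color

    # treatment zone disk
    tz_bool = _disk(h, w, params.tz_center_px, params.tz_radius_px)
    tz_color = _TZ_COLORS[bg_rng.integers(len(_TZ_COLORS))].astype(np.float32)
    img[tz_bool] = tz_color

    # pupil drawn last: a circle of near-black pixels overlapping the
    # treatment zone.  Rendered as strong attenuation of the underlying
    # map (like the alpha-blended overlays of topographer exports) so the
    # regions stay separable by contrast alone, which is all the
    # segmentation networks are meant to need from this stand-in
    pupil_bool = _disk(h, w, params.pupil_center_px, params.pupil_radius_px)
    attenuation = float(bg_rng.uniform(0.08, 0.18))
    img[pupil_bool] *= attenuation

    if params.noise_sd > 0:
        img = img + noise_rng.normal(0.0, params.noise_sd, img.shape)
    img = np.clip(img, 0, 255).astype(np.uint8)

    d_px = math.hypot(
        params.pupil_center_px[0] - params.tz_center_px[0],
        params.pupil_center_px[1] - params.tz_center_px[1],
    )
    true_ind = IndicatorSet(
        decentration_px=d_px,
        decentration_mm=d_px / params.px_per_mm,
        edcr=analytic_edcr(
            params.pupil_center_px, params.pupil_radius_px,
            params.tz_center_px, params.tz_radius_px,
        ),
        px_per_mm=params.px_per_mm,
    )
    return SyntheticCase(
        image=TopographyImage(img, px_per_mm=params.px_per_mm),
        pupil_mask=RegionMask(pupil_bool.astype(np.uint8), role=PUPIL),
        tz_mask=RegionMask(tz_bool.astype(np.uint8), role=TREATMENT_ZONE),
        true_indicators=true_ind,
        true_class=classify(true_ind),
        params=params,
    )


# ---------------------------------------------------------------------------
# dataset sampling

@dataclass
class ParamRanges:
    """Sampling ranges for dataset generation.

    By default cases cycle through the four classes in equal proportion;
    the target decentration/EDCR are drawn inside the class region with a
    safety margin from the decision boundaries (``margin_mm``,
    ``margin_edcr``) so that rasterisation cannot flip the
    construction-time label.  The treatment-zone radius is solved from the
    target EDCR via the circle-intersection law of cosines.  Set
    ``class_targets=None`` to sample decentration/EDCR uniformly from the
    stated ranges instead.
    """

    image_size_px: tuple[int, int] = (384, 384)
    px_per_mm: float = DEFAULT_PX_PER_MM
    pupil_radius_mm: tuple[float, float] = (1.1, 2.0)  # pediatric mesopic pupils
    decentration_mm: tuple[float, float] = (0.06, 1.45)
    edcr: tuple[float, float] = (0.03, 0.95)
    ring_width_px: tuple[float, float] = (25.0, 50.0)  # 0.5–1 mm steepened annulus
    noise_sd: tuple[float, float] = (2.0, 8.0)
    center_jitter_mm: float = 0.25
    class_targets: tuple[str, ...] | None = ("I", "II", "III", "IV")
    margin_mm: float = 0.10
    margin_edcr: float = 0.08
    # cap on the predicted EDCR discretisation error (see
    # _predicted_edcr_discretization_err): geometries whose rasterised
    # indicators could not track the analytic truth are resampled, because
    # the generator's contract is that ground truth survives rasterisation
    max_predicted_edcr_err: float = 0.045

    def validate(self) -> None:
        for name in ("pupil_radius_mm", "decentration_mm", "edcr",
                     "ring_width_px", "noise_sd"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValueError(f"empty range for {name}: ({lo}, {hi})")
        if self.pupil_radius_mm[0] <= 0:
            raise ValueError("pupil radius must be positive")
        if self.class_targets is not None and len(self.class_targets) == 0:
            raise ValueError("class_targets must be None or nonempty")


def _clip_interval(lo: float, hi: float, a: float, b: float) -> tuple[float, float]:
    lo2, hi2 = max(lo, a), min(hi, b)
    if hi2 < lo2:
        raise ValueError(
            f"requested ranges [{lo}, {hi}] do not intersect the class band [{a}, {b}]"
        )
    return lo2, hi2


def _target_bands(target: str | None, r: ParamRanges):
    """(decentration, edcr) sampling bands for a class target."""
    dlo, dhi = r.decentration_mm
    elo, ehi = r.edcr
    m, me = r.margin_mm, r.margin_edcr
    if target is None:
        return (dlo, dhi), (elo, ehi)
    if target == "I":
        return _clip_interval(dlo, dhi, 0.0, 1.0 - m), _clip_interval(elo, ehi, 0.75 + me, 1.0)
    if target == "II":
        return _clip_interval(dlo, dhi, 0.0, 1.0 - m), _clip_interval(elo, ehi, 0.25 + me, 0.75 - me)
    if target == "III":
        return _clip_interval(dlo, dhi, 1.0 + m, np.inf), (max(elo, 0.1), min(ehi, 0.9))
    # for the EDCR < 1/4 classes the discretisation bias on EDCR is strictly
    # downward (away from the 1/4 boundary), so a smaller margin suffices
    me_low = min(me, 0.04)
    if target == "IV":
        return _clip_interval(dlo, dhi, 0.0, 0.5 - m), _clip_interval(elo, ehi, 0.0, 0.25 - me_low)
    if target == "UNCLASSIFIED":
        return _clip_interval(dlo, dhi, 0.5 + m, 1.0 - m), _clip_interval(elo, ehi, 0.0, 0.25 - me_low)
    raise ValueError(f"unknown class target {target!r}")


def _solve_tz_radius(d: float, rp: float, f: float) -> float:
    """Treatment-zone radius achieving EDCR = f for pupil radius rp at
    center distance d (all px); inverse of :func:`analytic_edcr`."""
    half_angle = math.pi * (1.0 - f)
    rt_sq = d * d + rp * rp - 2.0 * d * rp * math.cos(half_angle)
    return math.sqrt(max(rt_sq, 0.0))


def _predicted_edcr_discretization_err(
    d: float, rp: float, rt: float, delta: float = 1.0
) -> float:
    """First-order bound on how far pixel-level EDCR can undershoot the
    analytic value.

    Four-neighborhood boundary pixels sit up to about one pixel inside the
    ideal pupil circle, so the measured covered/uncovered crossing happens
    at an effective pupil radius rp − delta; the bound is the resulting
    shift of the crossing angle as a fraction of π.  Near-tangent or
    near-concentric geometries make this large, which is why the dataset
    sampler rejects them.
    """
    if d < 1e-9 or rp - delta <= 0:
        return 0.0

    def phi(r_eff: float) -> float:
        c = (r_eff * r_eff + d * d - rt * rt) / (2.0 * r_eff * d)
        return math.acos(min(1.0, max(-1.0, c)))

    return max(0.0, (phi(rp - delta) - phi(rp)) / math.pi)


def _bbox_center(mask: np.ndarray) -> tuple[float, float]:
    ys, xs = np.nonzero(mask)
    return ((xs.min() + xs.max()) / 2.0, (ys.min() + ys.max()) / 2.0)


def generate_dataset(
    n: int,
    param_ranges: ParamRanges | None = None,
    seed: int = 0,
    include_gap: bool = False,
) -> list[SyntheticCase]:
    """Draw ``n`` cases deterministically from ``seed``.

    With the default ranges the cases cycle through classes I–IV (so any
    n ≥ 4 spans all four); ``include_gap=True`` additionally interleaves
    cases from the unassigned criterion-gap region (decentration in
    (0.5, 1] with EDCR < 1/4), labelled UNCLASSIFIED.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    r = param_ranges or ParamRanges()
    r.validate()
    rng = np.random.default_rng(seed)
    ppm = r.px_per_mm
    h, w = r.image_size_px
    targets = list(r.class_targets) if r.class_targets else [None]
    if include_gap and r.class_targets:
        targets = targets + ["UNCLASSIFIED"]
    cases: list[SyntheticCase] = []
    for i in range(n):
        target = targets[i % len(targets)]
        (dlo, dhi), (elo, ehi) = _target_bands(target, r)
        for _attempt in range(500):
            rp = rng.uniform(*r.pupil_radius_mm) * ppm
            d = rng.uniform(dlo, min(dhi, r.decentration_mm[1])) * ppm
            f = rng.uniform(elo, ehi)
            d = max(d, 2.0)  # avoid the degenerate concentric case
            rt = _solve_tz_radius(d, rp, f)
            ring = rng.uniform(*r.ring_width_px)
            if rt < 0.25 * ppm:
                continue  # implausibly small treatment zone; resample
            if (
                0.005 < f < 0.995
                and _predicted_edcr_discretization_err(d, rp, rt)
                > r.max_predicted_edcr_err
            ):
                continue  # rasterisation could not track the analytic EDCR
            # place the midpoint of the two centers near the canvas center
            jit = r.center_jitter_mm * ppm
            mx = w / 2 + rng.uniform(-jit, jit)
            my = h / 2 + rng.uniform(-jit, jit)
            theta = rng.uniform(0, 2 * np.pi)
            dx, dy = 0.5 * d * math.cos(theta), 0.5 * d * math.sin(theta)
            pc = (mx - dx, my - dy)
            tc = (mx + dx, my + dy)
            # pupil and treatment-zone disks must lie fully inside the
            # canvas; the ring may clip at the edge, as in clinical exports
            margin = 2.0
            if not (
                pc[0] - rp >= margin and pc[1] - rp >= margin
                and pc[0] + rp <= w - 1 - margin and pc[1] + rp <= h - 1 - margin
                and tc[0] - rt >= margin and tc[1] - rt >= margin
                and tc[0] + rt <= w - 1 - margin and tc[1] + rt <= h - 1 - margin
            ):
                continue
            params = CaseParams(
                image_size_px=(h, w),
                px_per_mm=ppm,
                pupil_center_px=pc,
                pupil_radius_px=rp,
                tz_center_px=tc,
                tz_radius_px=rt,
                ring_width_px=ring,
                noise_sd=rng.uniform(*r.noise_sd),
                background_seed=int(rng.integers(2**31)),
                rng_seed=int(rng.integers(2**31)),
            )
            case = generate_case(params)
            if target is not None and case.true_class.value != target:
                continue  # numerically landed outside the band; resample
            # the circumscribed-rectangle center of a rasterised disk is
            # quantised; reject the rare draw where the quantisation of the
            # two centers conspires against the 1 px recovery contract
            d_disc = math.hypot(
                *(np.subtract(_bbox_center(case.pupil_mask.pixels),
                              _bbox_center(case.tz_mask.pixels)))
            )
            if abs(d_disc - d) > 0.9:
                continue
            cases.append(case)
            break
        else:
            raise RuntimeError(
                f"could not sample a feasible case for target {target!r} "
                "within 500 attempts; ranges may be infeasible"
            )
    return cases
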