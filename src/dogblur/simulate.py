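"""Controlled blur degradations and MRI-like phantoms.

Two degradation families mirror the standard objective-evaluation protocol
for blur metrics: a rotationally symmetric Gaussian low-pass of window
width 3..15 pixels, and a linear camera-motion point-spread function whose
length (pixels) and angle (degrees) both equal the degradation level.
Levels run 0..15; level 0 is the identity.

Because real clinical volumes cannot ship with the package, a seeded
phantom generator produces piecewise-constant slices — nested elliptical
"anatomy" on a zero background (brain-like) or a disk with chamber
inclusions (cardiac-like).  Piecewise-constant images are the ideal-image
model of the quality metric, so a freshly generated phantom is the sharp
end of every degradation series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Literal

import numpy as np
from scipy import ndimage

__all__ = [
    "MAX_LEVEL",
    "DegradationSpec",
    "PhantomSpec",
    "gaussian_blur_width",
    "motion_psf",
    "apply_gaussian_blur",
    "apply_motion_blur",
    "apply_degradation",
    "generate_phantom",
    "degradation_series",
]

MAX_LEVEL = 15

BlurKind = Literal["gaussian", "motion"]


@dataclass(frozen=True)
class DegradationSpec:
    kind: BlurKind
    level: int

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "motion"):
            raise ValueError(f"unknown blur kind {self.kind!r}")
        _check_level(self.level)


def _check_level(level: int) -> int:
    if not (0 <= level <= MAX_LEVEL):
        raise ValueError(f"level must be in 0..{MAX_LEVEL}, got {level}")
    return int(level)


# ---------------------------------------------------------------------------
# Gaussian blur
# ---------------------------------------------------------------------------

def gaussian_blur_width(level: int) -> int:
    """Kernel window width for a degradation level.

    Levels 1..15 map linearly onto the width range 3..15 pixels and are
    rounded to the nearest odd integer, so w(1) = 3 and w(15) = 15.
    """
    _check_level(level)
    if level == 0:
        raise ValueError("level 0 is the identity; it has no kernel width")
    w = 3.0 + (level - 1) * 12.0 / 14.0
    return int(2 * round((w - 1.0) / 2.0) + 1)


def _gaussian_window_kernel(width: int) -> np.ndarray:
    # Rotationally symmetric low-pass on a fixed w x w support, sigma = w/6,
    # renormalized to unit sum.
    sigma = width / 6.0
    half = (width - 1) // 2
    x = np.arange(-half, half + 1, dtype=np.float64)
    xx, yy = np.meshgrid(x, x, indexing="ij")
    k = np.exp(-(xx * xx + yy * yy) / (2.0 * sigma * sigma))
    return k / k.sum()


def apply_gaussian_blur(image: np.ndarray, level: int) -> np.ndarray:
    """Convolve with the level's unit-sum Gaussian window (symmetric boundary)."""
    _check_level(level)
    arr = np.asarray(image, dtype=np.float64)
    if level == 0:
        return arr.copy()
    kernel = _gaussian_window_kernel(gaussian_blur_width(level))
    return ndimage.convolve(arr, kernel, mode="reflect")


# ---------------------------------------------------------------------------
# Motion blur
# ---------------------------------------------------------------------------

def motion_psf(length: float, angle_deg: float) -> np.ndarray:
    """Unit-sum PSF of linear camera motion.

    The PSF is a line segment of the given length (pixels) through the
    kernel center at the given angle (degrees, counterclockwise from the
    row axis), rasterized with anti-aliased weights: each pixel within
    the segment's extent contributes ``max(0, 1 - d)`` where d is its
    perpendicular distance to the line.
    """
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    if length == 1:
        return np.ones((1, 1))
    theta = math.radians(angle_deg)
    ux, uy = math.cos(theta), math.sin(theta)
    half = (length - 1) / 2.0
    r = int(math.ceil(half)) + 1
    coords = np.arange(-r, r + 1, dtype=np.float64)
    xx, yy = np.meshgrid(coords, coords, indexing="ij")
    # distance along and perpendicular to the motion direction
    t = xx * ux + yy * uy
    d_perp = np.abs(-xx * uy + yy * ux)
    within = np.abs(t) <= half
    # taper beyond the endpoints by distance to the nearest endpoint
    d_end = np.hypot(np.abs(t) - half, d_perp)
    dist = np.where(within, d_perp, d_end)
    k = np.maximum(0.0, 1.0 - dist)
    s = k.sum()
    if s <= 0:  # pragma: no cover - unreachable for length >= 1
        raise RuntimeError("degenerate motion PSF")
    # trim all-zero borders so the support is tight
    rows = np.flatnonzero(k.any(axis=1))
    cols = np.flatnonzero(k.any(axis=0))
    k = k[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]
    return k / s


def apply_motion_blur(image: np.ndarray, level: int) -> np.ndarray:
    """Convolve with a line PSF of length = angle = level (symmetric boundary)."""
    _check_level(level)
    arr = np.asarray(image, dtype=np.float64)
    if level == 0:
        return arr.copy()
    kernel = motion_psf(float(level), float(level))
    return ndimage.convolve(arr, kernel, mode="reflect")


def apply_degradation(image: np.ndarray, spec: DegradationSpec) -> np.ndarray:
    if spec.kind == "gaussian":
        return apply_gaussian_blur(image, spec.level)
    return apply_motion_blur(image, spec.level)


def degradation_series(
    image: np.ndarray, kind: BlurKind
) -> Iterator[tuple[int, np.ndarray]]:
    """Yield (level, degraded image) for levels 0..15; level 0 is the input."""
    if kind not in ("gaussian", "motion"):
        raise ValueError(f"unknown blur kind {kind!r}")
    for level in range(MAX_LEVEL + 1):
        yield level, apply_degradation(image, DegradationSpec(kind, level))


# ---------------------------------------------------------------------------
# Phantoms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for a seeded piecewise-constant phantom slice.

    The generated image holds exactly ``n_regions + 1`` distinct intensity
    values (the regions plus the zero background) and is a pure function
    of the spec: identical specs give bit-identical phantoms.
    """

    d1: int = 128
    d2: int = 128
    n_regions: int = 4
    intensity_levels: tuple[float, ...] | None = None
    seed: int = 0
    layout: Literal["brain", "cardiac"] = "brain"

    def __post_init__(self) -> None:
        if self.d1 < 64 or self.d2 < 64:
            raise ValueError(f"phantom dims must be >= 64x64, got {self.d1}x{self.d2}")
        if self.n_regions < 1:
            raise ValueError("n_regions must be >= 1")
        if self.layout not in ("brain", "cardiac"):
            raise ValueError(f"unknown layout {self.layout!r}")
        if self.intensity_levels is not None:
            levels = tuple(float(v) for v in self.intensity_levels)
            if len(levels) != self.n_regions:
                raise ValueError(
                    f"need {self.n_regions} intensity levels, got {len(levels)}"
                )
            if len(set(levels)) != len(levels) or 0.0 in levels:
                raise ValueError("intensity levels must be distinct and nonzero")
            if min(levels) < 0 or max(levels) > 255:
                raise ValueError("intensity levels must lie in [0, 255]")
            object.__setattr__(self, "intensity_levels", levels)


def _draw_levels(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.intensity_levels is not None:
        return np.asarray(spec.intensity_levels, dtype=np.float64)
    # distinct, nonzero, comfortably above background
    return rng.choice(np.arange(40, 256), size=spec.n_regions, replace=False).astype(
        np.float64
    )


def _ellipse_mask(
    d1: int, d2: int, cy: float, cx: float, a: float, b: float, phi: float
) -> np.ndarray:
    yy, xx = np.mgrid[0:d1, 0:d2]
    y = yy - cy
    x = xx - cx
    c, s = math.cos(phi), math.sin(phi)
    u = y * c + x * s
    v = -y * s + x * c
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def generate_phantom(spec: PhantomSpec) -> np.ndarray:
    """Render a phantom slice from its spec (deterministic per seed).

    Brain layout: nested ellipses shrinking toward the center, mild seeded
    jitter in aspect and orientation.  Cardiac layout: one large disk with
    smaller circular "chamber" inclusions.  A zero margin of at least 15%
    of each side separates anatomy from the grid border.
    """
    rng = np.random.default_rng(spec.seed)
    levels = _draw_levels(spec, rng)
    img = np.zeros((spec.d1, spec.d2), dtype=np.float64)
    cy, cx = (spec.d1 - 1) / 2.0, (spec.d2 - 1) / 2.0
    a0 = 0.32 * spec.d1
    b0 = 0.30 * spec.d2

    if spec.layout == "brain":
        if a0 / spec.n_regions < 2.5 or b0 / spec.n_regions < 2.5:
            raise ValueError(
                f"{spec.n_regions} nested regions do not fit in "
                f"{spec.d1}x{spec.d2}"
            )
        prev_a, prev_b = math.inf, math.inf
        for k in range(spec.n_regions):
            f = 1.0 - k / spec.n_regions
            # strict shrink guarantees every ring stays visible
            a = min(a0 * f * rng.uniform(0.95, 1.0), prev_a - 1.5)
            b = min(b0 * f * rng.uniform(0.95, 1.0), prev_b - 1.5)
            phi = rng.uniform(-0.2, 0.2)
            img[_ellipse_mask(spec.d1, spec.d2, cy, cx, a, b, phi)] = levels[k]
            prev_a, prev_b = a, b
    else:  # cardiac: disk + chambers
        n_chambers = spec.n_regions - 1
        r_outer = min(a0, b0)
        r_chamber = 0.22 * r_outer
        if n_chambers > 6 or (n_chambers > 0 and r_chamber < 2.5):
            raise ValueError(
                f"{spec.n_regions} cardiac regions do not fit in "
                f"{spec.d1}x{spec.d2}"
            )
        img[_ellipse_mask(spec.d1, spec.d2, cy, cx, r_outer, r_outer, 0.0)] = levels[0]
        phase = rng.uniform(0.0, 2.0 * math.pi)
        for k in range(n_chambers):
            ang = phase + 2.0 * math.pi * k / max(n_chambers, 1)
            ry = cy + 0.5 * r_outer * math.sin(ang)
            rx = cx + 0.5 * r_outer * math.cos(ang)
            img[_ellipse_mask(spec.d1, spec.d2, ry, rx, r_chamber, r_chamber, 0.0)] = (
                levels[k + 1]
            )

    return img
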