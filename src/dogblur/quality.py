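"""Six-step blind blur assessment for 2-D MRI slices.

The metric scores a single grayscale slice with no reference image.  The
slice is min-max rescaled to [0, 255], an anatomy foreground mask is
extracted by mean-thresholding, and the image is then pushed through two
parallel difference-of-Gaussian (DoG) filter banks over a shared multiscale
schedule s = 1..L:

* the *high-energy* bank ``(sigma_inner, sigma_outer) = (1, 1 + s)``
  progressively retains/highlights edge content, and
* the *low-energy* bank ``(s, s + 1)`` progressively attenuates it.

At every scale each filter response is converted to an edge map (a local
contrast image, by default the sample standard deviation in a 5x5 window)
and its mean over the foreground is recorded.  At the final scale the two
means, mu_CA (high energy) and mu_CB (low energy), satisfy
``mu_CB <= mu_CA`` and their distance ``D = |mu_CA - mu_CB|``, normalized
against the foreground mean mu_Id of the rescaled image, gives the two
standardized scores

    q1 = D / mu_Id                (contrast)
    q2 = D / (mu_Id + mu_CB)      (sharpness)
    Q  = (q1 + q2) / 2            (total quality, in [0, 1])

A perfectly sharp piecewise-constant image scores near 1; a detail-free
(e.g. constant) image scores exactly 0.  The whole pipeline is
deterministic and seed-free.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, NamedTuple

import numpy as np
from scipy import ndimage
from skimage.morphology import remove_small_objects

logger = logging.getLogger(__name__)

__all__ = [
    "EmptyForegroundError",
    "DoGParams",
    "MultiscaleConfig",
    "FeatureTrajectory",
    "QualityScore",
    "SliceAssessment",
    "MIN_DIM",
    "rescale_to_reference_range",
    "extract_foreground",
    "masked_mean",
    "gaussian_kernel",
    "dog_kernel",
    "scale_range",
    "local_contrast_map",
    "multiscale_trajectory",
    "predict_quality",
    "assess_image",
]

#: smallest slice side accepted by the pipeline
MIN_DIM = 16

REFERENCE_MAX = 255.0


class EmptyForegroundError(ValueError):
    """No foreground pixels survive thresholding and cleaning."""


class DoGParams(NamedTuple):
    """Widths (in pixels) of the two Gaussians forming one DoG kernel.

    ``sigma_inner == sigma_outer`` is permitted only as the degenerate
    zero-kernel case.
    """

    sigma_inner: float
    sigma_outer: float

    def validate(self) -> "DoGParams":
        if not (self.sigma_inner > 0):
            raise ValueError(f"sigma_inner must be > 0, got {self.sigma_inner}")
        if self.sigma_outer < self.sigma_inner:
            raise ValueError(
                f"sigma_outer ({self.sigma_outer}) must be >= sigma_inner "
                f"({self.sigma_inner})"
            )
        return self


@dataclass(frozen=True)
class MultiscaleConfig:
    """Filter schedule and edge-map parameters.

    Parameters
    ----------
    L:
        Scale count of the multiscale representation.  ``None`` means
        "derive from the image dimensions" via :func:`scale_range`.
    contrast_window:
        Odd side length of the local-contrast window (default 5, the
        recommended size for 256x256 and 512x512 slices).
    contrast_operator:
        ``"std"`` (sample standard deviation, default) or ``"range"``
        (max - min) within the window.
    min_component_area:
        Foreground components smaller than this many pixels are removed
        during mask cleaning (8-connectivity).
    """

    L: int | None = None
    contrast_window: int = 5
    contrast_operator: Literal["std", "range"] = "std"
    min_component_area: int = 800

    def __post_init__(self) -> None:
        if self.L is not None and self.L < 2:
            raise ValueError(f"L must be >= 2, got {self.L}")
        if self.contrast_window < 3 or self.contrast_window % 2 == 0:
            raise ValueError(
                f"contrast_window must be odd and >= 3, got {self.contrast_window}"
            )
        if self.contrast_operator not in ("std", "range"):
            raise ValueError(f"unknown contrast operator {self.contrast_operator!r}")
        if self.min_component_area < 0:
            raise ValueError("min_component_area must be >= 0")

    def high_energy_schedule(self, L: int) -> list[DoGParams]:
        """Edge-retaining bank: (1, 1+s) for s = 1..L."""
        return [DoGParams(1.0, 1.0 + s).validate() for s in range(1, L + 1)]

    def low_energy_schedule(self, L: int) -> list[DoGParams]:
        """Edge-attenuating bank: (s, s+1) for s = 1..L."""
        return [DoGParams(float(s), s + 1.0).validate() for s in range(1, L + 1)]


@dataclass(frozen=True)
class FeatureTrajectory:
    """Per-scale foreground means of both edge-map sequences.

    ``mu_high[s-1]`` / ``mu_low[s-1]`` are the edge-map means of the
    high- and low-energy filters at scale s; the final entries are the
    points A and B whose distance drives the quality score.
    """

    mu_reference: float
    mu_high: tuple[float, ...]
    mu_low: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.mu_high) != len(self.mu_low):
            raise ValueError("mu_high and mu_low must have equal length")
        if len(self.mu_high) < 2:
            raise ValueError("trajectory needs at least two scales")

    @property
    def L(self) -> int:
        return len(self.mu_high)

    @property
    def mu_ca(self) -> float:
        """Final high-energy edge-map mean (point A)."""
        return self.mu_high[-1]

    @property
    def mu_cb(self) -> float:
        """Final low-energy edge-map mean (point B)."""
        return self.mu_low[-1]

    @property
    def distance(self) -> float:
        """D = |mu_CA - mu_CB|."""
        return abs(self.mu_ca - self.mu_cb)


@dataclass(frozen=True)
class QualityScore:
    q1: float  # contrast quality score
    q2: float  # sharpness quality score
    Q: float  # total quality score, (q1 + q2) / 2


@dataclass(frozen=True)
class SliceAssessment:
    """Full result of :func:`assess_image` for one slice."""

    score: QualityScore
    trajectory: FeatureTrajectory
    mask: np.ndarray
    warnings: tuple[str, ...] = field(default=())


# ---------------------------------------------------------------------------
# Step 1: intensity standardization
# ---------------------------------------------------------------------------

def _as_slice(image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D slice, got shape {arr.shape}")
    if arr.shape[0] < MIN_DIM or arr.shape[1] < MIN_DIM:
        raise ValueError(
            f"slice must be at least {MIN_DIM}x{MIN_DIM}, got {arr.shape}"
        )
    if not np.all(np.isfinite(arr)):
        raise ValueError("slice contains non-finite pixel values")
    return arr


def rescale_to_reference_range(image: np.ndarray) -> np.ndarray:
    """Linearly map intensities onto [0, 255].

    A constant image has no range to stretch and maps to all zeros (the
    detail-free limit, which the downstream score treats as extremely
    degraded).
    """
    arr = _as_slice(image)
    lo = arr.min()
    hi = arr.max()
    if hi == lo:
        return np.zeros_like(arr)
    return (arr - lo) * (REFERENCE_MAX / (hi - lo))


# ---------------------------------------------------------------------------
# Step 2: foreground extraction
# ---------------------------------------------------------------------------

def extract_foreground(rescaled: np.ndarray, min_component_area: int = 800) -> np.ndarray:
    """Anatomy mask: mean threshold, hole filling, small-component removal.

    The global threshold sits at the first moment of the rescaled image;
    enclosed background holes are filled, then foreground connected
    components (8-connectivity) smaller than ``min_component_area`` pixels
    are dropped.

    Raises
    ------
    EmptyForegroundError
        If no component survives cleaning; the caller may retry with
        ``min_component_area=0``.
    """
    arr = _as_slice(rescaled)
    mask = arr >= arr.mean()
    mask = ndimage.binary_fill_holes(mask)
    if min_component_area > 1:
        # drop components with area < min_component_area (8-connectivity)
        mask = remove_small_objects(
            mask, max_size=min_component_area - 1, connectivity=2
        )
    if not mask.any():
        raise EmptyForegroundError(
            f"no foreground component of >= {min_component_area} px; "
            "retry with min_component_area=0"
        )
    return mask


# ---------------------------------------------------------------------------
# Step 3: foreground mean
# ---------------------------------------------------------------------------

def masked_mean(image: np.ndarray, mask: np.ndarray) -> float:
    """Arithmetic mean of ``image`` over the true pixels of ``mask``."""
    arr = np.asarray(image, dtype=np.float64)
    m = np.asarray(mask, dtype=bool)
    if arr.shape != m.shape:
        raise ValueError(f"shape mismatch: image {arr.shape} vs mask {m.shape}")
    n = int(m.sum())
    if n == 0:
        raise EmptyForegroundError("mask has no true pixels")
    return float(arr[m].sum() / n)


# ---------------------------------------------------------------------------
# Step 4: DoG kernels and multiscale filtering
# ---------------------------------------------------------------------------

def _gaussian_profile(sigma: float) -> np.ndarray:
    """Unit-sum 1-D Gaussian sampled on [-r, r], r = ceil(3*sigma)."""
    radius = math.ceil(3.0 * sigma)
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    g = np.exp(-(x * x) / (2.0 * sigma * sigma))
    return g / g.sum()


def gaussian_kernel(sigma: float) -> np.ndarray:
    """Isotropic 2-D Gaussian kernel, renormalized to unit sum.

    Support is the square of side ``2*ceil(3*sigma) + 1``.  The analytic
    normalization constant is irrelevant after renormalization, which also
    makes the difference of two such kernels sum exactly to zero.
    """
    if not sigma > 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    g = _gaussian_profile(sigma)
    return np.outer(g, g)


def dog_kernel(params: DoGParams) -> np.ndarray:
    """Difference-of-Gaussian kernel ``G(sigma_inner) - G(sigma_outer)``.

    The narrower kernel is zero-padded to the wider support; the result
    sums to zero (difference of two unit-sum kernels).
    """
    params = DoGParams(*params).validate()
    inner = gaussian_kernel(params.sigma_inner)
    outer = gaussian_kernel(params.sigma_outer)
    side = max(inner.shape[0], outer.shape[0])
    out = np.zeros((side, side), dtype=np.float64)

    def _add(k: np.ndarray, sign: float) -> None:
        off = (side - k.shape[0]) // 2
        out[off:off + k.shape[0], off:off + k.shape[1]] += sign * k

    _add(inner, 1.0)
    _add(outer, -1.0)
    return out


def scale_range(d1: int, d2: int) -> int:
    """Scale count ``L = floor(sqrt(d1 + d2) / 2)`` (never below 2)."""
    if d1 < MIN_DIM or d2 < MIN_DIM:
        raise ValueError(f"dimensions must be >= {MIN_DIM}, got ({d1}, {d2})")
    return max(2, math.floor(math.sqrt(d1 + d2) / 2.0))


def _smooth(image: np.ndarray, sigma: float) -> np.ndarray:
    # Separable passes with the same truncated unit-sum profile as
    # gaussian_kernel; symmetric boundary.  Exactly equals dense 2-D
    # convolution with the outer-product kernel.
    g = _gaussian_profile(sigma)
    tmp = ndimage.convolve1d(image, g, axis=0, mode="reflect")
    return ndimage.convolve1d(tmp, g, axis=1, mode="reflect")


def dog_response(image: np.ndarray, params: DoGParams) -> np.ndarray:
    """Convolve ``image`` with the DoG kernel (symmetric boundary)."""
    params = DoGParams(*params).validate()
    arr = np.asarray(image, dtype=np.float64)
    if params.sigma_inner == params.sigma_outer:
        return np.zeros_like(arr)
    return _smooth(arr, params.sigma_inner) - _smooth(arr, params.sigma_outer)


# ---------------------------------------------------------------------------
# Step 5: edge map (local contrast image)
# ---------------------------------------------------------------------------

def local_contrast_map(
    response: np.ndarray,
    window: int = 5,
    operator: Literal["std", "range"] = "std",
) -> np.ndarray:
    """Per-pixel local contrast of a raw (signed) DoG response.

    ``std`` computes the sample standard deviation and ``range`` the
    max - min spread within a ``window x window`` neighborhood under
    symmetric padding.  The output is nonnegative with the input's shape.
    """
    arr = np.asarray(response, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"expected 2-D response, got shape {arr.shape}")
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    if operator == "std":
        n = window * window
        # center by the global mean: E[x^2]-E[x]^2 is shift-invariant in
        # exact arithmetic but ill-conditioned far from zero
        centered = arr - arr.mean()
        mean = ndimage.uniform_filter(centered, size=window, mode="reflect")
        mean_sq = ndimage.uniform_filter(centered * centered, size=window, mode="reflect")
        var = np.maximum(mean_sq - mean * mean, 0.0) * (n / (n - 1))
        return np.sqrt(var)
    if operator == "range":
        hi = ndimage.maximum_filter(arr, size=window, mode="reflect")
        lo = ndimage.minimum_filter(arr, size=window, mode="reflect")
        return hi - lo
    raise ValueError(f"unknown contrast operator {operator!r}")


# ---------------------------------------------------------------------------
# Step 6 inputs: the feature trajectory
# ---------------------------------------------------------------------------

def multiscale_trajectory(
    rescaled: np.ndarray,
    mask: np.ndarray,
    config: MultiscaleConfig | None = None,
    L: int | None = None,
) -> FeatureTrajectory:
    """Run both filter banks over s = 1..L and record edge-map means.

    ``rescaled`` must be Step-1 output and ``mask`` its foreground;
    the mask is computed once and reused at every scale.
    """
    config = config or MultiscaleConfig()
    arr = _as_slice(rescaled)
    if L is None:
        L = config.L if config.L is not None else scale_range(*arr.shape)
    if L < 2:
        raise ValueError(f"L must be >= 2, got {L}")

    # Unique Gaussian widths across both schedules are 1..L+1; smooth once
    # per width, then form every DoG response by subtraction.
    smoothed = {s: _smooth(arr, float(s)) for s in range(1, L + 2)}

    mu_high: list[float] = []
    mu_low: list[float] = []
    for s in range(1, L + 1):
        resp_high = smoothed[1] - smoothed[1 + s]  # (1, 1+s)
        resp_low = smoothed[s] - smoothed[s + 1]  # (s, s+1)
        for resp, acc in ((resp_high, mu_high), (resp_low, mu_low)):
            edge = local_contrast_map(
                resp, window=config.contrast_window, operator=config.contrast_operator
            )
            acc.append(masked_mean(edge, mask))

    return FeatureTrajectory(
        mu_reference=masked_mean(arr, mask),
        mu_high=tuple(mu_high),
        mu_low=tuple(mu_low),
    )


# ---------------------------------------------------------------------------
# Step 6: quality index
# ---------------------------------------------------------------------------

def predict_quality(
    trajectory: FeatureTrajectory | tuple[float, float, float],
    warnings: list[str] | None = None,
) -> QualityScore:
    """Standardized quality index from the final edge-map means.

    Accepts either a :class:`FeatureTrajectory` or a bare
    ``(mu_ca, mu_cb, mu_reference)`` triple.  ``q1`` normalizes the
    distance by the image mean, ``q2`` by the image mean plus mu_CB; both
    are clamped to [0, 1] (clamping and ordering violations are logged and
    appended to ``warnings`` when provided).  A zero reference mean means a
    detail-free image and scores (0, 0, 0).
    """
    if isinstance(trajectory, FeatureTrajectory):
        mu_ca, mu_cb, mu_id = trajectory.mu_ca, trajectory.mu_cb, trajectory.mu_reference
    else:
        mu_ca, mu_cb, mu_id = trajectory

    def _warn(msg: str) -> None:
        logger.warning(msg)
        if warnings is not None:
            warnings.append(msg)

    if mu_id <= 0.0:
        if mu_id < 0.0:
            raise ValueError(f"reference mean must be >= 0, got {mu_id}")
        _warn("zero reference mean (detail-free image); score forced to 0")
        return QualityScore(0.0, 0.0, 0.0)

    if mu_cb > mu_ca + 1e-9:
        _warn(f"ordering violation: mu_CB={mu_cb:.6g} > mu_CA={mu_ca:.6g}")

    dist = abs(mu_ca - mu_cb)
    q1 = dist / mu_id
    q2 = dist / (mu_id + mu_cb)
    if q1 > 1.0 or q2 > 1.0:
        _warn(f"validity bound exceeded (q1={q1:.6g}, q2={q2:.6g}); clamped")
    q1 = min(max(q1, 0.0), 1.0)
    q2 = min(max(q2, 0.0), 1.0)
    return QualityScore(q1, q2, (q1 + q2) / 2.0)


def assess_image(
    image: np.ndarray,
    config: MultiscaleConfig | None = None,
) -> SliceAssessment:
    """Score one slice: Steps 1-6 composed.

    Deterministic: identical input and config give bit-identical output.
    If foreground cleaning empties the mask, the assessment retries with
    ``min_component_area=0`` and records a warning.
    """
    config = config or MultiscaleConfig()
    warnings: list[str] = []

    rescaled = rescale_to_reference_range(image)
    try:
        mask = extract_foreground(rescaled, config.min_component_area)
    except EmptyForegroundError:
        warnings.append(
            f"no foreground component >= {config.min_component_area} px; "
            "retried with min_component_area=0"
        )
        mask = extract_foreground(rescaled, 0)

    trajectory = multiscale_trajectory(rescaled, mask, config)
    score = predict_quality(trajectory, warnings=warnings)
    return SliceAssessment(
        score=score, trajectory=trajectory, mask=mask, warnings=tuple(warnings)
    )
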