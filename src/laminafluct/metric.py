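"""The rim fluctuation index and envelope intensity profiles.

The fluctuation index quantifies how punctate a test channel (lamin A/C or
prelamin A) is relative to a reference channel (lamin B) along the nuclear
envelope.  Given both channels sampled at the same contour points:

1. the first derivative of each intensity profile along the (circular)
   contour is computed and normalized by its maximum absolute value;
2. the per-position ratio of derivative magnitudes is taken in both
   directions (reference/test and test/reference), divide-by-zero corrected,
   and each ratio array is min-max normalized to [0, 1];
3. the fraction of positions with normalized ratio above a threshold
   (default 0.15) is expressed as a percentage for each direction, and the
   two percentages are added.

A test channel whose spatial distribution is identical to the reference
yields an index of exactly 0 (the ratio array is constant, so the min-max
step maps it to all zeros); increasingly punctate test patterns drive the
index up, toward its ceiling of 200.

Divide-by-zero rule: where both derivatives are zero the ratio is 1 (the
continuous limit of equal derivatives — required for the exact index-0
identity on every profile); where only the denominator is zero the ratio is
set to the maximum finite ratio in that direction (1.0 if none exists).

The module also provides the linescan profiles used for display: intensity
along a user-drawn segment across the envelope, each channel scaled so its
maximum is 100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .contours import NucleusContour
from .errors import ContractError, GeometryError
from .stacks import Image2D


@dataclass
class IntensityProfile:
    """Intensities sampled along a contour (circular) or a line segment."""

    values: np.ndarray
    positions: np.ndarray | None = None
    circular: bool = True

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 1:
            raise ContractError("profile values must be 1D")
        if not np.isfinite(v).all():
            raise ContractError("profile values must be finite")
        if self.circular and len(v) < 4:
            raise ContractError("circular profiles need at least 4 samples")
        self.values = v

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class FluctuationResult:
    """Per-nucleus fluctuation index with all intermediates."""

    index: float
    fraction_12: float  # percent of positions with normalized ref/test ratio above threshold
    fraction_21: float  # percent for test/ref
    derivative_ref: np.ndarray
    derivative_test: np.ndarray
    ratio_12: np.ndarray  # min-max normalized, in [0, 1]
    ratio_21: np.ndarray
    threshold: float


def sample_contour_intensity(image: Image2D | np.ndarray, contour: NucleusContour) -> IntensityProfile:
    """Bilinear interpolation of the channel at each contour point, in order."""
    data = image.data if isinstance(image, Image2D) else np.asarray(image, dtype=np.float64)
    h, w = data.shape
    y, x = contour.y, contour.x
    if (y.min() < 0) or (y.max() > h - 1) or (x.min() < 0) or (x.max() > w - 1):
        raise GeometryError("contour points fall outside the image")
    values = ndimage.map_coordinates(data, [y, x], order=1, mode="nearest")
    return IntensityProfile(values=values, positions=contour.points.copy(), circular=True)


def circular_derivative(profile: IntensityProfile | np.ndarray) -> np.ndarray:
    """Central differences with wraparound: d[i] = (v[i+1] - v[i-1]) / 2."""
    if isinstance(profile, IntensityProfile):
        if not profile.circular:
            raise ContractError("circular_derivative requires a circular profile")
        v = profile.values
    else:
        v = np.asarray(profile, dtype=np.float64)
    if len(v) < 3:
        raise ContractError("need at least 3 samples for a circular derivative")
    return (np.roll(v, -1) - np.roll(v, 1)) / 2.0


def normalize_signal(values: np.ndarray, mode: str) -> np.ndarray:
    """Normalize an array; constant input maps to all zeros in both modes.

    ``max_abs`` divides by the maximum absolute value (derivative stage);
    ``min_max`` maps to [0, 1] via (x - min) / (max - min) (ratio stage).
    """
    v = np.asarray(values, dtype=np.float64)
    if not np.isfinite(v).all():
        raise ContractError("cannot normalize non-finite values")
    if mode == "max_abs":
        m = np.abs(v).max()
        return np.zeros_like(v) if m == 0 else v / m
    if mode == "min_max":
        lo, hi = v.min(), v.max()
        return np.zeros_like(v) if hi == lo else (v - lo) / (hi - lo)
    raise ContractError(f"unknown normalization mode {mode!r}")


def directional_ratio(numerator: np.ndarray, denominator: np.ndarray) -> np.ndarray:
    """Per-position ratio of derivative magnitudes with divide-by-zero correction.

    both zero -> 1; x/0 with x > 0 -> the maximum finite ratio in this
    direction (1.0 when no finite ratio exists).
    """
    a = np.abs(np.asarray(numerator, dtype=np.float64))
    b = np.abs(np.asarray(denominator, dtype=np.float64))
    out = np.empty_like(a)
    ok = b > 0
    out[ok] = a[ok] / b[ok]
    finite_max = out[ok].max() if ok.any() else 1.0
    both_zero = (~ok) & (a == 0)
    over_zero = (~ok) & (a > 0)
    out[both_zero] = 1.0
    out[over_zero] = finite_max
    return out


def fluctuation_index(
    ref: IntensityProfile | np.ndarray,
    test: IntensityProfile | np.ndarray,
    threshold: float = 0.15,
) -> FluctuationResult:
    """Compute the fluctuation index from paired envelope profiles.

    Both profiles must be circular, of equal length >= 8, and sampled at the
    same contour positions.  See the module docstring for the three steps.
    """
    ref_v = ref.values if isinstance(ref, IntensityProfile) else np.asarray(ref, dtype=np.float64)
    test_v = test.values if isinstance(test, IntensityProfile) else np.asarray(test, dtype=np.float64)
    for p in (ref, test):
        if isinstance(p, IntensityProfile) and not p.circular:
            raise ContractError("fluctuation_index requires circular contour profiles")
    if len(ref_v) != len(test_v):
        raise ContractError(f"profile lengths differ: {len(ref_v)} vs {len(test_v)}")
    if len(ref_v) < 8:
        raise ContractError("fluctuation index is unstable below 8 positions")

    d_ref = normalize_signal(circular_derivative(ref_v), "max_abs")
    d_test = normalize_signal(circular_derivative(test_v), "max_abs")

    r12 = normalize_signal(directional_ratio(d_ref, d_test), "min_max")
    r21 = normalize_signal(directional_ratio(d_test, d_ref), "min_max")

    frac12 = 100.0 * float(np.mean(r12 > threshold))
    frac21 = 100.0 * float(np.mean(r21 > threshold))
    return FluctuationResult(
        index=frac12 + frac21,
        fraction_12=frac12,
        fraction_21=frac21,
        derivative_ref=d_ref,
        derivative_test=d_test,
        ratio_12=r12,
        ratio_21=r21,
        threshold=threshold,
    )


def linescan_profile(
    images: list[Image2D | np.ndarray],
    p0: tuple[float, float],
    p1: tuple[float, float],
    n_samples: int = 100,
) -> list[IntensityProfile]:
    """Normalized intensity profiles along a segment, one per channel.

    Samples ``n_samples`` evenly spaced points from ``p0`` to ``p1`` (each
    (y, x)) by bilinear interpolation and scales each channel so its maximum
    is 100.  A constant positive channel maps to all 100; an all-zero
    channel stays zero.
    """
    p0 = np.asarray(p0, dtype=np.float64)
    p1 = np.asarray(p1, dtype=np.float64)
    if np.allclose(p0, p1):
        raise GeometryError("degenerate linescan segment: endpoints coincide")
    t = np.linspace(0.0, 1.0, n_samples)
    pts = p0[None, :] + t[:, None] * (p1 - p0)[None, :]
    profiles = []
    for img in images:
        data = img.data if isinstance(img, Image2D) else np.asarray(img, dtype=np.float64)
        h, w = data.shape
        if (pts[:, 0].min() < 0) or (pts[:, 0].max() > h - 1) or (pts[:, 1].min() < 0) or (pts[:, 1].max() > w - 1):
            raise GeometryError("linescan endpoints fall outside an image")
        raw = ndimage.map_coordinates(data, [pts[:, 0], pts[:, 1]], order=1, mode="nearest")
        peak = raw.max()
        values = raw * (100.0 / peak) if peak > 0 else np.zeros_like(raw)
        profiles.append(IntensityProfile(values=values, positions=pts.copy(), circular=False))
    return profiles
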