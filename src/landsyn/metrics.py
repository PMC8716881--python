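"""Spatiotemporal synergy metrics: FWHM, CoA, overlaps, coactivation index.

All temporal metrics operate on motor primitives defined on the fixed
300-point landing cycle (100 flight + 200 stance points). The cycle is
treated as circular for the center of activity, so a primitive wrapping
around the cycle boundary gets a meaningful center.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import DataError
from .muscles import EXTENSORS, FLEXORS, JOINTS, MUSCLES, muscle_indices

CYCLE_POINTS = 300


def _as_primitive(series, n_points: int | None = None) -> np.ndarray:
    x = np.asarray(series, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        raise DataError("primitive contains non-finite values")
    if n_points is not None and x.size != n_points:
        raise DataError(f"expected a {n_points}-point series, got {x.size}")
    return x


def half_max_mask(series) -> np.ndarray:
    """Boolean mask of points strictly exceeding the half maximum.

    The cycle minimum is subtracted before thresholding, so the mask is
    invariant to a positive affine transform of the series.
    """
    x = _as_primitive(series)
    shifted = x - x.min()
    peak = shifted.max()
    if peak == 0.0:
        warnings.warn("constant primitive: empty half-max mask", stacklevel=2)
        return np.zeros(x.size, dtype=bool)
    return shifted > peak / 2.0


def fwhm(series) -> int:
    """Full width at half maximum, in cycle points.

    Counts every point whose minimum-subtracted value strictly exceeds half
    the (minimum-subtracted) maximum. Non-contiguous supra-threshold lobes
    all contribute, so a bimodal primitive gets the summed width of its
    lobes. A constant series has zero width (with a warning).
    """
    return int(np.count_nonzero(half_max_mask(series)))


def coa(series, subtract_min: bool = False) -> float:
    """Center of activity of a primitive, in cycle points on [0, 300).

    The cycle is mapped onto the unit circle (point t -> angle
    2*pi*(t-1)/300 for t = 1..300) and the primitive is treated as a mass
    distribution; the CoA is the angle of its circular mean resultant,
    converted back to points. A symmetric bump centred at point c returns c;
    mass split across the cycle boundary wraps correctly.

    ``subtract_min`` optionally removes the cycle minimum before weighting
    (the default keeps raw values, mirroring the FWHM-only use of the
    minimum subtraction).
    """
    x = _as_primitive(series)
    if subtract_min:
        x = x - x.min()
    total = x.sum()
    if total <= 0 or np.ptp(x) == 0.0:
        raise DataError("CoA undefined for constant or zero-mass primitive")
    n = x.size
    theta = 2.0 * np.pi * np.arange(n) / n
    angle = np.arctan2((x * np.sin(theta)).sum(), (x * np.cos(theta)).sum())
    angle %= 2.0 * np.pi
    return float((angle / (2.0 * np.pi) * n + 1.0) % n)


@dataclass(frozen=True)
class PrimitiveMetrics:
    """FWHM, CoA and the half-max mask of a single motor primitive."""

    fwhm: int
    coa: float
    half_max_mask: np.ndarray = field(repr=False)


def primitive_metrics(series, subtract_min_for_coa: bool = False) -> PrimitiveMetrics:
    mask = half_max_mask(series)
    return PrimitiveMetrics(
        fwhm=int(np.count_nonzero(mask)),
        coa=coa(series, subtract_min=subtract_min_for_coa),
        half_max_mask=mask,
    )


@dataclass(frozen=True)
class OverlapProfile:
    """Pointwise concurrency of primitives above their half maxima."""

    overlap_count: np.ndarray
    overlap_indicator: np.ndarray


def overlaps(primitives) -> OverlapProfile:
    """Overlap profile of a set of primitives.

    At each cycle point, counts how many primitives exceed their own
    (minimum-subtracted) half maximum; an overlap happens wherever at least
    two do so simultaneously. With a single primitive the indicator is all
    false by definition.
    """
    P = np.atleast_2d(np.asarray(primitives, dtype=float))
    masks = np.vstack([half_max_mask(row) for row in P])
    count = masks.sum(axis=0).astype(int)
    return OverlapProfile(overlap_count=count, overlap_indicator=count >= 2)


@dataclass(frozen=True)
class CoactivationIndex:
    """Flexor/extensor balance of a motor module at one joint.

    ``cai`` is 0 with extensor-only drive, 1 with flexor-only drive and 0.5
    at full coactivation. ``flexor_mean`` and ``extensor_mean`` are the
    group means after the pairwise normalization forcing them to sum to 1.
    """

    joint: str
    cai: float
    flexor_mean: float
    extensor_mean: float


def coactivation_index(
    module,
    joint: str,
    muscle_labels: tuple[str, ...] = MUSCLES,
) -> CoactivationIndex:
    """Coactivation index CaI = Flex / (Flex + Ext) for one joint.

    ``module`` is a nonnegative muscle-weight vector ordered like
    ``muscle_labels``. Flex and Ext are the means of the fixed flexor and
    extensor muscle groups of the joint (hip: FL+RF vs ME+MA; knee: ST+BF vs
    RF+VM+VL; ankle: TA vs PL+GM+GL+SO).
    """
    if joint not in JOINTS:
        raise KeyError(f"unknown joint {joint!r}; expected one of {JOINTS}")
    w = np.asarray(module, dtype=float).ravel()
    if w.size != len(muscle_labels):
        raise DataError(
            f"module has {w.size} weights for {len(muscle_labels)} muscle labels"
        )
    if np.any(w < 0):
        raise DataError("module weights must be nonnegative")
    flex = float(w[muscle_indices(muscle_labels, FLEXORS[joint])].mean())
    ext = float(w[muscle_indices(muscle_labels, EXTENSORS[joint])].mean())
    total = flex + ext
    if total == 0.0:
        raise DataError(f"CaI undefined at {joint}: no flexor or extensor activity")
    return CoactivationIndex(
        joint=joint,
        cai=flex / total,
        flexor_mean=flex / total,
        extensor_mean=ext / total,
    )
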