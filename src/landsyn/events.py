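"""GRF-based landing segmentation, time normalization, and kinetic scalars.

A landing is segmented from the vertical ground reaction force alone:
touchdown is the first sample strictly exceeding 20 N, the analysis window
opens 300 ms before touchdown (flight) and closes at the first sample that
enters the body-weight +/- 2.5% band after the first vertical-GRF local
minimum following the impact peak (stance). Every channel is then resampled
onto a fixed 300-point cycle: 100 points of flight and 200 of stance,
concatenated, so the touchdown falls at point 101 of every trial and the
roughly 1:2 flight-to-stance duration ratio of a drop landing is respected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import DataError, SegmentationError

FLIGHT_POINTS = 100
STANCE_POINTS = 200
CYCLE_POINTS = FLIGHT_POINTS + STANCE_POINTS

TOUCHDOWN_THRESHOLD_N = 20.0
BODYWEIGHT_BAND = 0.025
PRE_TOUCHDOWN_S = 0.3


@dataclass(frozen=True)
class LandingSegmentation:
    """Sample indices delimiting one landing's interval of interest."""

    touchdown_index: int
    interval_start_index: int
    stance_end_index: int
    rate: float = 1000.0

    def __post_init__(self):
        if not (self.interval_start_index < self.touchdown_index < self.stance_end_index):
            raise SegmentationError(
                "segmentation must satisfy interval_start < touchdown < stance_end"
            )

    @property
    def stance_duration(self) -> float:
        """Stance duration in seconds."""
        return (self.stance_end_index - self.touchdown_index) / self.rate


@dataclass(frozen=True)
class NormalizedTrial:
    """All channels of one landing on the fixed 300-point cycle."""

    emg: np.ndarray = field(repr=False)
    grf_norm: np.ndarray = field(repr=False)
    condition: str = "SG"
    cop: np.ndarray | None = field(default=None, repr=False)
    angles: np.ndarray | None = field(default=None, repr=False)
    moments: np.ndarray | None = field(default=None, repr=False)
    flight_points: int = FLIGHT_POINTS
    stance_points: int = STANCE_POINTS

    def __post_init__(self):
        n = self.flight_points + self.stance_points
        if self.emg.shape[1] != n or self.grf_norm.shape[-1] != n:
            raise DataError(f"normalized channels must have exactly {n} points")


def detect_touchdown(vgrf, rate: float = 1000.0,
                     threshold: float = TOUCHDOWN_THRESHOLD_N) -> int:
    """First sample of the vertical GRF strictly crossing the 20 N threshold.

    Returns the smallest index i with vgrf[i] > threshold and
    vgrf[i-1] <= threshold. Flight noise touching the threshold exactly does
    not trigger (strict inequality).
    """
    v = np.asarray(vgrf, dtype=float).ravel()
    if v.size < 2:
        raise SegmentationError("vertical GRF series too short")
    if v[0] > threshold:
        raise SegmentationError("series starts above the touchdown threshold")
    above = v > threshold
    if not above.any():
        raise SegmentationError(f"vertical GRF never exceeds {threshold} N")
    return int(np.argmax(above))


def detect_stance_end(vgrf, touchdown: int, bodyweight: float,
                      band: float = BODYWEIGHT_BAND) -> int:
    """First sample entering the BW +/- 2.5% band after the post-impact minimum.

    The vertical GRF of a landing follows a peak-dip-settle shape: the
    search starts at the impact peak (maximum after touchdown), finds the
    first strict local minimum after it, and returns the first subsequent
    sample whose value lies inside [ (1-band)*BW, (1+band)*BW ].
    """
    if bodyweight <= 0:
        raise SegmentationError("bodyweight must be positive")
    v = np.asarray(vgrf, dtype=float).ravel()
    if not 0 <= touchdown < v.size - 2:
        raise SegmentationError("touchdown index outside series")
    peak = touchdown + int(np.argmax(v[touchdown:]))
    interior = np.arange(peak + 1, v.size - 1)
    is_min = (v[interior] < v[interior - 1]) & (v[interior] < v[interior + 1])
    if not is_min.any():
        raise SegmentationError("no vertical-GRF minimum after the impact peak")
    minimum = int(interior[np.argmax(is_min)])
    lo, hi = (1.0 - band) * bodyweight, (1.0 + band) * bodyweight
    in_band = (v[minimum:] >= lo) & (v[minimum:] <= hi)
    if not in_band.any():
        raise SegmentationError(
            "vertical GRF never enters the body-weight band after the minimum"
        )
    return minimum + int(np.argmax(in_band))


def segment_landing(vgrf, bodyweight: float, rate: float = 1000.0,
                    threshold: float = TOUCHDOWN_THRESHOLD_N,
                    band: float = BODYWEIGHT_BAND) -> LandingSegmentation:
    """Full segmentation: touchdown, 300 ms pre-touchdown start, stance end."""
    touchdown = detect_touchdown(vgrf, rate=rate, threshold=threshold)
    pre = int(rate * PRE_TOUCHDOWN_S)
    if touchdown < pre:
        raise SegmentationError(
            f"needs {pre} samples before touchdown, trial has {touchdown}"
        )
    stance_end = detect_stance_end(vgrf, touchdown, bodyweight, band=band)
    return LandingSegmentation(
        touchdown_index=touchdown,
        interval_start_index=touchdown - pre,
        stance_end_index=stance_end,
        rate=rate,
    )


def _resample_phase(channels: np.ndarray, start: int, stop: int, n_out: int) -> np.ndarray:
    """Linearly resample channels[:, start:stop+1] onto n_out points."""
    if stop - start < 1:
        raise SegmentationError("phase has fewer than 2 samples")
    pos = np.linspace(start, stop, n_out)
    base = np.arange(start, stop + 1)
    seg = channels[:, start:stop + 1]
    return np.vstack([np.interp(pos, base, row) for row in seg])


def time_normalize_channels(channels, seg: LandingSegmentation,
                            flight_points: int = FLIGHT_POINTS,
                            stance_points: int = STANCE_POINTS) -> np.ndarray:
    """Resample channels (rows) onto the concatenated 300-point cycle.

    Flight (interval start up to the last pre-touchdown sample) maps to 100
    points and stance (touchdown through stance end) to 200 points, pasted
    one after another. Interpolation is linear, so affine signals are
    resampled exactly; the first stance point is the touchdown sample.
    """
    X = np.atleast_2d(np.asarray(channels, dtype=float))
    if seg.stance_end_index >= X.shape[1]:
        raise DataError("segmentation indices exceed channel length")
    flight = _resample_phase(X, seg.interval_start_index, seg.touchdown_index - 1,
                             flight_points)
    stance = _resample_phase(X, seg.touchdown_index, seg.stance_end_index,
                             stance_points)
    return np.hstack([flight, stance])


def time_normalize(emg, vgrf_3d, seg: LandingSegmentation, condition: str = "SG",
                   cop=None, angles=None, moments=None) -> NormalizedTrial:
    """Build a NormalizedTrial from raw channels and a segmentation.

    ``vgrf_3d`` is the 3-component GRF (3 x samples); its Euclidean norm is
    the force channel kept on the cycle. Optional CoP, joint-angle and
    joint-moment channels share the same segmentation.
    """
    grf = np.atleast_2d(np.asarray(vgrf_3d, dtype=float))
    grf_norm = np.linalg.norm(grf, axis=0) if grf.shape[0] > 1 else grf[0]
    out = {}
    for name, chan in (("cop", cop), ("angles", angles), ("moments", moments)):
        out[name] = None if chan is None else time_normalize_channels(chan, seg)
    return NormalizedTrial(
        emg=time_normalize_channels(emg, seg),
        grf_norm=time_normalize_channels(grf_norm, seg)[0],
        condition=condition,
        cop=out["cop"],
        angles=out["angles"],
        moments=out["moments"],
    )


def cop_ellipse_area(cop, coverage: float = 0.95) -> float:
    """Area of the 95% confidence ellipse of a 2-D CoP point cloud, in m^2.

    The smallest ellipse expected to contain ``coverage`` of the points
    under a bivariate normal model has area
    ``pi * chi2_2(coverage) * sqrt(det(S))`` with S the 2x2 sample
    covariance; chi2_2(0.95) = 5.991. Degenerate (collinear or repeated)
    clouds yield zero area with a warning.
    """
    pts = np.asarray(cop, dtype=float)
    if pts.ndim != 2:
        raise DataError("CoP must be a 2-D array")
    if pts.shape[0] == 2 and pts.shape[1] != 2:
        pts = pts.T
    if pts.shape[0] < 3:
        raise DataError("need at least 3 CoP points")
    cov = np.cov(pts, rowvar=False)
    eigvals = np.linalg.eigvalsh(cov)
    if np.any(eigvals <= 0):
        warnings.warn("degenerate CoP covariance: zero ellipse area", stacklevel=2)
        return 0.0
    q = stats.chi2.ppf(coverage, df=2)
    return float(np.pi * q * np.sqrt(eigvals.prod()))


@dataclass(frozen=True)
class MomentScalars:
    """Stance-phase scalars of one joint-moment (and optional angle) series."""

    max: float
    time_to_peak: float | None
    rate: float | None
    range_of_motion: float | None
    rate_undefined: bool = False


def moment_scalars(moment, seg: LandingSegmentation, angle=None) -> MomentScalars:
    """Joint-moment maxima, timing and rate of development over the stance.

    * ``max``: moment maximum between touchdown and stance end.
    * ``time_to_peak``: seconds from touchdown to that maximum.
    * ``rate``: max / time_to_peak (Nm/s); undefined (flagged) when the
      peak occurs at touchdown.
    * ``range_of_motion``: angle at touchdown minus the stance minimum of
      the angle series, when an angle series is supplied.
    """
    m = np.asarray(moment, dtype=float).ravel()
    if not seg.touchdown_index < m.size:
        raise DataError("touchdown outside the moment series")
    stance = slice(seg.touchdown_index, min(seg.stance_end_index + 1, m.size))
    seg_vals = m[stance]
    peak_offset = int(np.argmax(seg_vals))
    peak_val = float(seg_vals[peak_offset])
    ttp = peak_offset / seg.rate
    undefined = peak_offset == 0
    if undefined:
        warnings.warn("moment peak at touchdown: rate undefined", stacklevel=2)
    rom = None
    if angle is not None:
        a = np.asarray(angle, dtype=float).ravel()
        rom = float(a[seg.touchdown_index] - a[stance].min())
    return MomentScalars(
        max=peak_val,
        time_to_peak=None if undefined else ttp,
        rate=None if undefined else peak_val / ttp,
        range_of_motion=rom,
        rate_undefined=undefined,
    )
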