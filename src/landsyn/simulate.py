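"""Synthetic single-leg-landing trials with known synergy ground truth.

The generator builds, for one landing at a time:

* **EMG** — three (by default) ground-truth synergies, each a truncated
  Gaussian motor primitive on the 300-point landing cycle combined with a
  nonnegative motor-module weighting over the 13 muscles. The cycle-domain
  envelopes M @ P are mapped back onto the trial's own time axis (300 ms of
  flight, a condition-dependent stance) and multiplied with zero-mean white
  carriers band-passed 20-450 Hz, so the raw signal has realistic spectral
  content and survives the 50 Hz high-pass of the conditioning chain.
  Envelope noise is additive Gaussian truncated at zero, parameterized by
  an SNR in dB.
* **GRF** — the canonical flight -> impact transient -> dip -> settling
  shape: near-zero vertical force in flight, a sharp impact peak, a
  post-impact minimum, then an exponential approach into the body-weight
  +/- 2.5% band. The unstable condition (UG) has a lower, slower impact
  transient and a longer stance, mirroring landings on foam.
* **CoP** — a mean-reverting 2-D stochastic walk during stance whose
  stationary dispersion is condition-scaled (smaller on the unstable foam).

Every trial records its exact touchdown sample and full ground truth, so
each downstream stage is testable without external data. One global seed
fans out to per-trial substreams; cohorts are bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .exceptions import ConfigurationError, DataError
from .muscles import MUSCLES, N_MUSCLES

CYCLE_POINTS = 300
FLIGHT_POINTS = 100
RATE_HZ = 1000.0

# Default ground-truth modules (13 muscles x 3 synergies). Columns follow the
# three functional synergies of a single-leg landing: touchdown (plantar
# flexors dominant, pre-activation before impact), weight acceptance (knee
# extensors), stabilization (hamstrings, dorsiflexors, hip muscles).
DEFAULT_MODULES = np.array([
    #  TD    WA    ST
    [0.15, 0.40, 0.55],  # ME
    [0.10, 0.35, 0.45],  # MA
    [0.20, 0.30, 0.50],  # FL
    [0.25, 0.90, 0.20],  # RF
    [0.20, 1.00, 0.25],  # VM
    [0.25, 0.95, 0.25],  # VL
    [0.15, 0.20, 0.85],  # ST
    [0.20, 0.25, 0.90],  # BF
    [0.45, 0.15, 0.70],  # TA
    [0.80, 0.20, 0.65],  # PL
    [0.95, 0.30, 0.30],  # GM
    [0.90, 0.25, 0.25],  # GL
    [1.00, 0.35, 0.40],  # SO
])

# Primitive centers/widths in cycle points: touchdown peaks late in flight,
# weight acceptance shortly after impact, stabilization mid-stance. Widths
# are on the scale of the FWHM values observed in landing primitives.
DEFAULT_CENTERS = (90.0, 120.0, 210.0)
DEFAULT_WIDTHS = (55.0, 60.0, 80.0)

# Stance durations (s): means/SDs of single-leg drop landings per condition.
STANCE_DURATION_S = {"SG": (0.491, 0.062), "UG": (0.629, 0.085)}
# Impact peak (multiples of BW) and rise time (s): foam lowers and slows the
# post-touchdown force development.
IMPACT_PEAK_BW = {"SG": 3.2, "UG": 2.4}
IMPACT_RISE_S = {"SG": 0.045, "UG": 0.065}
# Stationary CoP dispersion (m): smaller sway area on the foam.
COP_SD_M = {"SG": 0.010, "UG": 0.006}

FWHM_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # FWHM = 2.355 sigma


@dataclass(frozen=True)
class GroundTruth:
    """True synergy structure behind one synthetic trial."""

    modules_true: np.ndarray = field(repr=False)
    centers: tuple[float, ...] = DEFAULT_CENTERS
    widths: tuple[float, ...] = DEFAULT_WIDTHS
    amplitudes: tuple[float, ...] = (1.0, 1.0, 1.0)
    noise_snr: float | None = 20.0
    n_muscles: int = N_MUSCLES
    condition: str = "SG"
    seed: int | None = None

    def __post_init__(self):
        M = np.asarray(self.modules_true, dtype=float)
        object.__setattr__(self, "modules_true", M)
        p = M.shape[1]
        if np.any(M < 0):
            raise ConfigurationError("ground-truth modules must be nonnegative")
        if not 1 <= p < self.n_muscles:
            raise ConfigurationError(f"need 1 <= p < {self.n_muscles}, got {p}")
        if len(self.centers) != p or len(self.widths) != p:
            raise ConfigurationError("one center and width per synergy required")
        if any(w <= 0 for w in self.widths):
            raise ConfigurationError("primitive widths must be positive")
        if any(not 1 <= c <= CYCLE_POINTS for c in self.centers):
            raise ConfigurationError("primitive centers must lie in [1, 300]")
        if self.condition not in ("SG", "UG"):
            raise ConfigurationError("condition must be 'SG' or 'UG'")

    @property
    def p_true(self) -> int:
        return self.modules_true.shape[1]

    def primitives(self, n_points: int = CYCLE_POINTS) -> np.ndarray:
        """True motor primitives (p x n_points), unit maximum each."""
        return np.vstack([
            a * generate_primitive(c, w, n_points)
            for c, w, a in zip(self.centers, self.widths, self.amplitudes)
        ])


@dataclass(frozen=True)
class SyntheticTrial:
    """One synthetic landing: raw streams plus ground truth."""

    emg_raw: np.ndarray = field(repr=False)
    grf: np.ndarray = field(repr=False)
    cop: np.ndarray = field(repr=False)
    touchdown_sample_true: int = 0
    bodyweight: float = 700.0
    rate: float = RATE_HZ
    condition: str = "SG"
    ground_truth: GroundTruth | None = None

    @property
    def n_samples(self) -> int:
        return self.emg_raw.shape[1]

    @property
    def vgrf(self) -> np.ndarray:
        return self.grf[2]


def generate_primitive(center: float, width: float,
                       n_points: int = CYCLE_POINTS) -> np.ndarray:
    """Truncated-Gaussian motor primitive on the cycle, unit peak.

    ``width`` is the full width at half maximum in cycle points
    (sigma = width / 2.355); the bump is truncated at the cycle edges and
    renormalized so the sample nearest ``center`` equals exactly 1.
    """
    if width <= 0:
        raise ConfigurationError("primitive width must be positive")
    if not 1 <= center <= n_points:
        raise ConfigurationError(f"center {center} outside [1, {n_points}]")
    t = np.arange(1, n_points + 1, dtype=float)
    sigma = width / FWHM_SIGMA
    bump = np.exp(-0.5 * ((t - center) / sigma) ** 2)
    nearest = int(np.clip(round(center), 1, n_points)) - 1
    return bump / bump[nearest]


def _bandpass_carrier(rng: np.random.Generator, shape, rate: float,
                      band=(20.0, 450.0)) -> np.ndarray:
    """Zero-mean unit-RMS white noise band-passed to the EMG band."""
    white = rng.standard_normal(shape)
    hi = min(band[1], 0.99 * rate / 2.0)
    sos = sps.butter(4, (band[0], hi), btype="bandpass", fs=rate, output="sos")
    carrier = sps.sosfiltfilt(sos, white, axis=-1)
    rms = np.sqrt(np.mean(carrier**2, axis=-1, keepdims=True))
    return carrier / rms


def _envelope_to_time(env_cycle: np.ndarray, touchdown: int, stance_end: int,
                      n_samples: int, rate: float, baseline: float) -> np.ndarray:
    """Map cycle-domain envelopes onto the trial's sample axis.

    Flight points 1..100 span the 300 ms before touchdown, stance points
    101..300 span touchdown..stance_end; outside the interval of interest
    the envelope relaxes linearly to the baseline tonus over 100 ms.
    """
    pre = int(rate * 0.3)
    pos = np.concatenate([
        np.linspace(touchdown - pre, touchdown - 1, FLIGHT_POINTS),
        np.linspace(touchdown, stance_end, CYCLE_POINTS - FLIGHT_POINTS),
    ])
    samples = np.arange(n_samples, dtype=float)
    out = np.vstack([np.interp(samples, pos, row) for row in env_cycle])
    ramp = int(0.1 * rate)
    left = np.clip((samples - (touchdown - pre - ramp)) / ramp, 0.0, 1.0)
    right = np.clip(((stance_end + ramp) - samples) / ramp, 0.0, 1.0)
    taper = left * right
    return baseline + (out - baseline) * taper


def synthesize_emg(gt: GroundTruth, touchdown: int, stance_end: int,
                   n_samples: int, rng: np.random.Generator,
                   rate: float = RATE_HZ, baseline: float = 0.02,
                   gain: float = 0.5) -> np.ndarray:
    """Raw synergy-structured EMG (muscles x n_samples), mV-like units.

    Envelopes are M_true @ P_true on the cycle, mapped to the time axis,
    degraded with truncated additive Gaussian noise at ``gt.noise_snr`` dB
    (None or inf disables noise), and multiplied with band-limited zero-mean
    carriers. The raw signal is therefore zero-mean and its linear envelope
    recovers the planted synergy structure.
    """
    env_cycle = gt.modules_true @ gt.primitives()
    env = _envelope_to_time(env_cycle, touchdown, stance_end, n_samples,
                            rate, baseline)
    env = np.clip(env, baseline * 0.25, None)
    if gt.noise_snr is not None and np.isfinite(gt.noise_snr):
        # noise lives in the envelope band (<= the 20 Hz envelope low-pass),
        # so the stated SNR is the SNR the conditioning chain actually sees
        sos = sps.butter(4, 20.0, btype="lowpass", fs=rate, output="sos")
        noise = sps.sosfiltfilt(sos, rng.standard_normal(env.shape), axis=-1)
        noise /= np.sqrt(np.mean(noise**2, axis=1, keepdims=True))
        power = np.mean(env**2, axis=1, keepdims=True)
        sd = np.sqrt(power / 10.0 ** (gt.noise_snr / 10.0))
        env = np.clip(env + sd * noise, 0.0, None)
    carrier = _bandpass_carrier(rng, env.shape, rate)
    raw = gain * env * carrier
    # AC-coupled amplifier: no DC offset survives acquisition
    return raw - raw.mean(axis=1, keepdims=True)


def synthesize_mechanics(condition: str, bodyweight: float,
                         rng: np.random.Generator, rate: float = RATE_HZ):
    """GRF (3 x n) and CoP (2 x n) series with a known touchdown sample.

    Returns ``(grf, cop, touchdown, stance_end_nominal, n_samples)``. The
    vertical force stays below 20 N throughout flight, first exceeds it at
    exactly the returned touchdown sample, peaks, dips to a post-impact
    minimum, and settles into the body-weight +/- 2.5% band.
    """
    if bodyweight <= 0:
        raise ConfigurationError("bodyweight must be positive")
    if condition not in STANCE_DURATION_S:
        raise ConfigurationError("condition must be 'SG' or 'UG'")
    mean_s, sd_s = STANCE_DURATION_S[condition]
    stance_s = float(np.clip(rng.normal(mean_s, sd_s), 0.35, 0.9))
    touchdown = int(rate * 0.36)
    stance_n = int(rate * stance_s)
    tail = int(rate * 0.1)
    n = touchdown + stance_n + tail + 1
    v = np.empty(n)
    # flight: rectified sensor noise well under the 20 N threshold
    v[:touchdown] = np.clip(np.abs(rng.normal(0.0, 3.0, touchdown)), 0.0, 15.0)

    peak = IMPACT_PEAK_BW[condition] * bodyweight
    t_peak = int(IMPACT_RISE_S[condition] * rate)
    dip_frac = 0.55 if condition == "SG" else 0.60
    dip = dip_frac * bodyweight
    t_dip = int(0.13 * rate)

    rise = np.linspace(0.0, np.pi / 2.0, t_peak)
    v[touchdown:touchdown + t_peak] = 25.0 + (peak - 25.0) * np.sin(rise)
    fall = np.linspace(0.0, np.pi, t_dip - t_peak)
    v[touchdown + t_peak:touchdown + t_dip] = \
        dip + (peak - dip) * (1.0 + np.cos(fall)) / 2.0
    # exponential settle whose nominal band entry is at stance_n
    k = np.arange(n - touchdown - t_dip, dtype=float)
    tau = max(stance_n - t_dip, 1) / np.log((bodyweight - dip) /
                                            (0.025 * bodyweight))
    v[touchdown + t_dip:] = bodyweight - (bodyweight - dip) * np.exp(-k / tau)
    # smooth low-frequency noise, small against the 2.5% band
    sos = sps.butter(2, 8.0, btype="lowpass", fs=rate, output="sos")
    wobble = sps.sosfiltfilt(sos, rng.standard_normal(n))
    wobble *= 0.004 * bodyweight / max(np.abs(wobble).max(), 1e-12)
    v[touchdown + t_peak:] += wobble[touchdown + t_peak:]

    shear_sd = 0.04 * bodyweight
    shear = sps.sosfiltfilt(sos, rng.standard_normal((2, n))) * shear_sd
    shear[:, :touchdown] *= 0.05
    grf = np.vstack([shear, v[None, :]])

    # CoP: AR(1) mean-reverting walk during stance, condition-scaled sd
    rho = 0.995
    sd = COP_SD_M[condition]
    innov = sd * np.sqrt(1.0 - rho**2)
    cop = np.zeros((2, n))
    for i in range(touchdown + 1, n):
        cop[:, i] = rho * cop[:, i - 1] + innov * rng.standard_normal(2)
    return grf, cop, touchdown, touchdown + stance_n, n


def _jittered_ground_truth(base: GroundTruth, rng: np.random.Generator,
                           center_jitter: float, width_jitter: float,
                           module_jitter: float, seed: int) -> GroundTruth:
    p = base.p_true
    centers = tuple(
        float(np.clip(c + rng.normal(0.0, center_jitter), 5, CYCLE_POINTS - 5))
        for c in base.centers)
    widths = tuple(
        float(np.clip(w + rng.normal(0.0, width_jitter), 10.0, 200.0))
        for w in base.widths)
    amps = tuple(float(rng.uniform(0.85, 1.15)) for _ in range(p))
    M = base.modules_true * rng.lognormal(0.0, module_jitter,
                                          base.modules_true.shape)
    return GroundTruth(
        modules_true=M, centers=centers, widths=widths, amplitudes=amps,
        noise_snr=base.noise_snr, n_muscles=base.n_muscles,
        condition=base.condition, seed=seed,
    )


def make_trial(gt: GroundTruth, bodyweight: float = 700.0,
               rate: float = RATE_HZ) -> SyntheticTrial:
    """Generate one full trial (EMG + GRF + CoP) from explicit ground truth."""
    rng = np.random.default_rng(gt.seed)
    grf, cop, touchdown, stance_end, n = synthesize_mechanics(
        gt.condition, bodyweight, rng, rate=rate)
    emg = synthesize_emg(gt, touchdown, stance_end, n, rng, rate=rate)
    return SyntheticTrial(
        emg_raw=emg, grf=grf, cop=cop, touchdown_sample_true=touchdown,
        bodyweight=bodyweight, rate=rate, condition=gt.condition,
        ground_truth=gt,
    )


def make_cohort(n_trials: int, condition: str = "SG", seed: int | None = None,
                noise_snr: float | None = 20.0,
                modules: np.ndarray | None = None,
                centers: tuple[float, ...] = DEFAULT_CENTERS,
                widths: tuple[float, ...] = DEFAULT_WIDTHS,
                bodyweight: float = 700.0,
                center_jitter: float = 5.0, width_jitter: float = 5.0,
                module_jitter: float = 0.10) -> list[SyntheticTrial]:
    """Generate a seeded cohort of trials with jittered ground truth.

    Trial-to-trial variability (primitive center/width jitter, amplitude
    and module weight variation) emulates the natural variability of
    repeated landings around a stable underlying synergy organization.
    """
    if n_trials < 1:
        raise ConfigurationError("n_trials must be >= 1")
    base = GroundTruth(
        modules_true=DEFAULT_MODULES if modules is None else modules,
        centers=centers, widths=widths,
        amplitudes=(1.0,) * len(centers),
        noise_snr=noise_snr, condition=condition,
    )
    streams = np.random.SeedSequence(seed).spawn(n_trials)
    trials = []
    for i, stream in enumerate(streams):
        sub = np.random.default_rng(stream)
        trial_seed = int(sub.integers(2**31))
        gt = _jittered_ground_truth(base, sub, center_jitter, width_jitter,
                                    module_jitter, trial_seed)
        trials.append(make_trial(gt, bodyweight=bodyweight))
    return trials


# ---------------------------------------------------------------------------
# fixture i/o: one directory per trial, wide CSV per stream + JSON sidecar

def write_trial(trial: SyntheticTrial, directory) -> Path:
    """Write a trial as CSV streams plus a JSON ground-truth sidecar."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    t = np.arange(trial.n_samples) / trial.rate
    pd.DataFrame(
        {"time": t, **{m: trial.emg_raw[i] for i, m in enumerate(MUSCLES)}}
    ).to_csv(d / "emg.csv", index=False)
    pd.DataFrame(
        {"time": t, "fx": trial.grf[0], "fy": trial.grf[1], "fz": trial.grf[2]}
    ).to_csv(d / "grf.csv", index=False)
    pd.DataFrame(
        {"time": t, "x": trial.cop[0], "y": trial.cop[1]}
    ).to_csv(d / "cop.csv", index=False)
    meta = {
        "condition": trial.condition,
        "bodyweight": trial.bodyweight,
        "rate": trial.rate,
        "touchdown_sample_true": trial.touchdown_sample_true,
    }
    if trial.ground_truth is not None:
        gt = asdict(trial.ground_truth)
        gt["modules_true"] = trial.ground_truth.modules_true.tolist()
        meta["ground_truth"] = gt
    (d / "trial.json").write_text(json.dumps(meta, indent=1))
    return d


def read_trial(directory) -> SyntheticTrial:
    """Read a trial written by :func:`write_trial`."""
    d = Path(directory)
    meta = json.loads((d / "trial.json").read_text())
    emg = pd.read_csv(d / "emg.csv")
    grf = pd.read_csv(d / "grf.csv")
    cop = pd.read_csv(d / "cop.csv")
    missing = [m for m in MUSCLES if m not in emg.columns]
    if missing:
        raise DataError(f"emg.csv lacks muscle columns {missing}")
    gt = None
    if "ground_truth" in meta:
        g = meta["ground_truth"]
        gt = GroundTruth(
            modules_true=np.asarray(g["modules_true"], dtype=float),
            centers=tuple(g["centers"]), widths=tuple(g["widths"]),
            amplitudes=tuple(g["amplitudes"]), noise_snr=g["noise_snr"],
            n_muscles=g["n_muscles"], condition=g["condition"],
            seed=g["seed"],
        )
    return SyntheticTrial(
        emg_raw=emg[list(MUSCLES)].to_numpy().T,
        grf=grf[["fx", "fy", "fz"]].to_numpy().T,
        cop=cop[["x", "y"]].to_numpy().T,
        touchdown_sample_true=int(meta["touchdown_sample_true"]),
        bodyweight=float(meta["bodyweight"]),
        rate=float(meta["rate"]),
        condition=meta["condition"],
        ground_truth=gt,
    )
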