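"""Surface-EMG conditioning and amplitude normalization.

The conditioning chain is the standard linear-envelope recipe for lower-limb
surface EMG: a 4th-order zero-phase Butterworth high-pass at 50 Hz to remove
movement artefact and baseline drift, full-wave rectification, and a
4th-order zero-phase Butterworth low-pass at 20 Hz to obtain the envelope.
Both filters are realized as second-order sections and applied
forward-backward (``sosfiltfilt``), which doubles the effective order and
cancels phase distortion; "4th order" refers to the single-pass design.

Amplitude normalization is participant-specific: each muscle is divided by
its maximum activity across that participant's stable-ground (SG) reference
series, so SG envelopes peak at 1.0 per muscle and unstable-ground trials
may exceed 1.0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import signal as sps
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import ConfigurationError, DataError, NormalizationError
from .muscles import MUSCLES


@dataclass(frozen=True)
class EmgEnvelope:
    """Nonnegative EMG envelopes, muscles x samples, at a fixed rate."""

    values: np.ndarray = field(repr=False)
    muscle_labels: tuple[str, ...] = MUSCLES
    rate: float = 1000.0
    flagged_muscles: tuple[str, ...] = ()

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2:
            raise DataError("envelope values must be a 2-D muscles x samples array")
        if v.shape[0] != len(self.muscle_labels):
            raise DataError(
                f"{v.shape[0]} envelope rows for {len(self.muscle_labels)} labels"
            )
        if len(set(self.muscle_labels)) != len(self.muscle_labels):
            raise DataError("muscle labels must be unique")

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


class EmgConditioner(TransformerMixin, BaseEstimator):
    """High-pass -> full-wave rectify -> low-pass EMG envelope extractor.

    Parameters
    ----------
    rate : float
        Sampling rate in Hz (must exceed twice the high-pass cutoff).
    highpass, lowpass : float
        Cutoff frequencies in Hz of the zero-phase Butterworth filters.
    order : int
        Single-pass design order of both filters; forward-backward
        application doubles it.
    """

    def __init__(self, rate: float = 1000.0, highpass: float = 50.0,
                 lowpass: float = 20.0, order: int = 4):
        self.rate = rate
        self.highpass = highpass
        self.lowpass = lowpass
        self.order = order

    def _check_params(self):
        if self.rate <= 2.0 * self.highpass:
            raise ConfigurationError(
                f"rate {self.rate} Hz must exceed twice the {self.highpass} Hz cutoff"
            )
        if self.rate <= 2.0 * self.lowpass:
            raise ConfigurationError(
                f"rate {self.rate} Hz must exceed twice the {self.lowpass} Hz cutoff"
            )
        if self.order < 1:
            raise ConfigurationError("filter order must be >= 1")

    def fit(self, X, y=None):
        """Stateless; validates parameters only."""
        self._check_params()
        self.n_features_in_ = np.atleast_2d(np.asarray(X)).shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        """Condition raw EMG (muscles x samples) into nonnegative envelopes."""
        self._check_params()
        raw = np.atleast_2d(np.asarray(X, dtype=float))
        if raw.shape[0] < 1 or raw.shape[1] < 2:
            raise DataError("need at least one muscle and two samples")
        if not np.all(np.isfinite(raw)):
            raise DataError("raw EMG contains non-finite samples")
        sos_hp = sps.butter(self.order, self.highpass, btype="highpass",
                            fs=self.rate, output="sos")
        sos_lp = sps.butter(self.order, self.lowpass, btype="lowpass",
                            fs=self.rate, output="sos")
        high = sps.sosfiltfilt(sos_hp, raw, axis=1)
        env = sps.sosfiltfilt(sos_lp, np.abs(high), axis=1)
        # filtfilt of a rectified signal can undershoot slightly; envelopes
        # are nonnegative by contract
        return np.clip(env, 0.0, None)


def condition_emg(
    raw,
    rate: float = 1000.0,
    muscle_labels: tuple[str, ...] = MUSCLES,
    highpass: float = 50.0,
    lowpass: float = 20.0,
    order: int = 4,
) -> EmgEnvelope:
    """Apply the EMG conditioning chain and wrap the result as an envelope."""
    cond = EmgConditioner(rate=rate, highpass=highpass, lowpass=lowpass, order=order)
    values = cond.fit(raw).transform(raw)
    if values.shape[0] != len(muscle_labels):
        raise DataError(
            f"{values.shape[0]} EMG rows for {len(muscle_labels)} muscle labels"
        )
    return EmgEnvelope(values=values, muscle_labels=muscle_labels, rate=rate)


def reference_maxima(reference: Iterable[EmgEnvelope]) -> np.ndarray:
    """Per-muscle maxima over all samples of all reference envelopes."""
    refs = list(reference)
    if not refs:
        raise NormalizationError("empty reference collection")
    labels = refs[0].muscle_labels
    for r in refs:
        if r.muscle_labels != labels:
            raise NormalizationError("reference trials have mismatched muscle sets")
    return np.max([r.values.max(axis=1) for r in refs], axis=0)


def normalize_amplitude(
    env: EmgEnvelope,
    reference: Sequence[EmgEnvelope],
) -> EmgEnvelope:
    """Divide each muscle by its maximum over the reference (SG) series.

    A muscle whose reference maximum is zero cannot be normalized: it is
    left unscaled and flagged on the returned envelope (with a warning)
    rather than divided.
    """
    maxima = reference_maxima(reference)
    if env.muscle_labels != reference[0].muscle_labels:
        raise NormalizationError("trial and reference muscle sets differ")
    zero = maxima == 0.0
    if np.any(zero):
        flagged = tuple(m for m, z in zip(env.muscle_labels, zero) if z)
        warnings.warn(
            f"all-zero reference for muscles {flagged}; left unnormalized",
            stacklevel=2,
        )
    else:
        flagged = ()
    scale = np.where(zero, 1.0, maxima)
    return replace(env, values=env.values / scale[:, None], flagged_muscles=flagged)
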