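"""Declarative run configuration for the landing-synergy pipeline.

Every analysis constant is a named key so sensitivity analyses are
one-flag changes: the 20 N touchdown threshold, the body-weight band, the
rank-selection and elbow MSE bounds, filter cutoffs, restart counts and
the global seed all live here. Defaults equal the analysis constants of
the method.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .exceptions import ConfigurationError


@dataclass
class RunConfig:
    # cohort / simulation
    seed: int = 0
    n_trials: int = 25
    conditions: tuple[str, ...] = ("SG", "UG")
    noise_snr: float | None = 20.0
    bodyweight: float = 700.0
    drop_first_last: bool = False

    # EMG conditioning
    rate: float = 1000.0
    highpass_hz: float = 50.0
    lowpass_hz: float = 20.0
    filter_order: int = 4

    # segmentation
    touchdown_threshold_n: float = 20.0
    bodyweight_band: float = 0.025

    # extraction
    nmf_restarts: int = 10
    nmf_tol: float = 1e-5
    nmf_patience: int = 20
    nmf_max_iter: int = 1000
    rank_mse_threshold: float = 1e-5

    # classification
    kmeans_restarts: int = 20
    elbow_mse_threshold: float = 1e-3
    score_tol: float = 0.05
    min_agreement: float = 0.5

    # metrics
    cop_coverage: float = 0.95
    coa_subtract_min: bool = False

    def __post_init__(self):
        self.conditions = tuple(self.conditions)
        positive = {
            "n_trials": self.n_trials, "rate": self.rate,
            "highpass_hz": self.highpass_hz, "lowpass_hz": self.lowpass_hz,
            "filter_order": self.filter_order,
            "touchdown_threshold_n": self.touchdown_threshold_n,
            "bodyweight_band": self.bodyweight_band,
            "nmf_restarts": self.nmf_restarts,
            "rank_mse_threshold": self.rank_mse_threshold,
            "kmeans_restarts": self.kmeans_restarts,
            "elbow_mse_threshold": self.elbow_mse_threshold,
            "bodyweight": self.bodyweight,
        }
        for name, value in positive.items():
            if value is None or value <= 0:
                raise ConfigurationError(f"{name} must be positive, got {value}")
        for c in self.conditions:
            if c not in ("SG", "UG"):
                raise ConfigurationError(f"unknown condition {c!r}")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def with_overrides(self, **kwargs) -> "RunConfig":
        data = asdict(self)
        data.update({k: v for k, v in kwargs.items() if v is not None})
        return RunConfig(**data)
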