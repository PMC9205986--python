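"""Study configuration for synthetic covert-attention experiments.

A :class:`StudyConfig` captures every generative parameter of a simulated
eye-tracking + EEG study: trial structure, fixational-eye-movement statistics,
the lateralized alpha (8-12 Hz) modulation, and behavioural outcomes. All
randomness downstream derives from ``seed``, so a config fully determines a
study.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

__all__ = ["DistributionSpec", "StudyConfig", "ConfigError"]


class ConfigError(ValueError):
    """Raised when a configuration field is invalid; names the field."""


@dataclass(frozen=True)
class DistributionSpec:
    """A small declarative univariate distribution.

    Supported families:

    ``truncnorm``
        params: ``mean``, ``sd``, ``low``, ``high`` (rejection-free via scipy).
    ``lognormal``
        params: ``median``, ``sigma`` and optional ``low``/``high`` truncation
        (truncation by resampling).
    ``uniform``
        params: ``low``, ``high``.
    """

    family: str
    params: dict[str, float]

    def support(self) -> tuple[float, float]:
        p = self.params
        if self.family == "truncnorm":
            return p["low"], p["high"]
        if self.family == "uniform":
            return p["low"], p["high"]
        if self.family == "lognormal":
            return p.get("low", 0.0), p.get("high", np.inf)
        raise ConfigError(f"unknown distribution family: {self.family!r}")

    def mean(self) -> float:
        """Approximate mean of the distribution (used for latent timing)."""
        lo, hi = self.support()
        if self.family == "uniform":
            return 0.5 * (lo + hi)
        if self.family == "truncnorm":
            from scipy import stats

            p = self.params
            a = (lo - p["mean"]) / p["sd"]
            b = (hi - p["mean"]) / p["sd"]
            return float(stats.truncnorm.mean(a, b, loc=p["mean"], scale=p["sd"]))
        # lognormal: numeric mean of the (possibly truncated) distribution
        rng = np.random.default_rng(0)
        return float(np.mean(self.sample(rng, 20000)))

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        p = self.params
        if self.family == "uniform":
            return rng.uniform(p["low"], p["high"], size)
        if self.family == "truncnorm":
            from scipy import stats

            a = (p["low"] - p["mean"]) / p["sd"]
            b = (p["high"] - p["mean"]) / p["sd"]
            u = rng.uniform(0.0, 1.0, size)
            return stats.truncnorm.ppf(u, a, b, loc=p["mean"], scale=p["sd"])
        if self.family == "lognormal":
            mu = np.log(p["median"])
            x = rng.lognormal(mu, p["sigma"], size)
            lo, hi = p.get("low", 0.0), p.get("high", np.inf)
            bad = (x < lo) | (x > hi)
            while bad.any():
                x[bad] = rng.lognormal(mu, p["sigma"], int(bad.sum()))
                bad = (x < lo) | (x > hi)
            return x
        raise ConfigError(f"unknown distribution family: {self.family!r}")

    def to_dict(self) -> dict[str, Any]:
        return {"family": self.family, "params": dict(self.params)}

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "DistributionSpec":
        return cls(family=d["family"], params=dict(d["params"]))


def _default_latency() -> DistributionSpec:
    # attentional-selection latency within the 200-600 ms window of interest
    return DistributionSpec("truncnorm", {"mean": 380.0, "sd": 90.0, "low": 200.0, "high": 600.0})


def _default_magnitude() -> DistributionSpec:
    # shift magnitudes in % of item eccentricity; mass concentrated below
    # 17.5% (1 degree at 5.7 degree eccentricity), floor at the 1% threshold
    return DistributionSpec("lognormal", {"median": 5.0, "sigma": 0.7, "low": 1.0, "high": 110.0})


def _default_behaviour() -> dict[str, Any]:
    return {
        "error_mean_deg": {"toward": 13.65, "none": 14.0, "away": 14.72},
        "error_sd_deg": 8.0,
        "error_participant_sd_deg": 2.0,
        "rt_mean_ms": 900.0,
        "rt_sd_ms": 250.0,
        "rt_participant_sd_ms": 100.0,
    }


@dataclass
class StudyConfig:
    """Generative parameters of a synthetic covert spatial-attention study.

    Defaults emulate the structure of a retro-cue working-memory experiment:
    two memory items at 5.7 degrees eccentricity, a central selection cue,
    directionally biased microsaccades in a 200-600 ms post-cue window, and a
    contralateral attenuation of posterior alpha power whose onset co-varies
    with microsaccade latency.
    """

    n_participants: int = 23
    n_trials: int = 1200
    sampling_rate: float = 1000.0
    epoch_window: tuple[float, float] = (-1000.0, 2000.0)
    item_eccentricity_deg: float = 5.7

    # microsaccade plan
    p_shift_in_window: float = 0.8
    p_toward_given_shift: float = 0.667
    p_second_shift: float = 0.2
    background_shift_rate: float = 1.0  # mean shifts/trial outside the window
    latency_distribution: DistributionSpec = field(default_factory=_default_latency)
    magnitude_distribution: DistributionSpec = field(default_factory=_default_magnitude)
    saccade_duration_ms: float = 20.0
    drift_noise_sd: float = 0.03  # % units per sample (random walk)
    eye_noise_sd: float = 0.1  # % units sample-to-sample jitter, per eye
    blink_rate: float = 0.3  # expected blinks per trial

    # alpha generator
    alpha_freq: float = 10.0
    alpha_amplitude: float = 1.0
    alpha_modulation_depth: float = 0.3
    away_modulation_scale: float = 0.5
    alpha_onset_lag: float = 50.0  # ms from attentional selection to modulation
    alpha_ramp_ms: float = 200.0
    noise_exponent: float = 1.0  # 1/f^exponent background
    eeg_noise_amplitude: float = 0.5

    behaviour_effects: dict[str, Any] = field(default_factory=_default_behaviour)
    calibration_noise_sd_deg: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        probs = {
            "p_shift_in_window": self.p_shift_in_window,
            "p_toward_given_shift": self.p_toward_given_shift,
            "p_second_shift": self.p_second_shift,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {p}")
        if self.n_participants < 2:
            raise ConfigError(f"n_participants must be >= 2, got {self.n_participants}")
        if self.n_trials < 1:
            raise ConfigError(f"n_trials must be >= 1, got {self.n_trials}")
        if self.sampling_rate <= 0:
            raise ConfigError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        t0, t1 = self.epoch_window
        if t1 <= t0:
            raise ConfigError(f"epoch_window must be increasing, got {self.epoch_window}")
        lo, hi = self.latency_distribution.support()
        if lo < t0 or hi > t1:
            raise ConfigError(
                f"latency_distribution support [{lo}, {hi}] must lie within the epoch {self.epoch_window}"
            )
        if not 0.0 <= self.alpha_modulation_depth < 1.0:
            raise ConfigError(
                f"alpha_modulation_depth must lie in [0, 1), got {self.alpha_modulation_depth}"
            )
        if self.item_eccentricity_deg <= 0:
            raise ConfigError(
                f"item_eccentricity_deg must be > 0, got {self.item_eccentricity_deg}"
            )

    # ------------------------------------------------------------------ io
    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["latency_distribution"] = self.latency_distribution.to_dict()
        d["magnitude_distribution"] = self.magnitude_distribution.to_dict()
        d["epoch_window"] = list(self.epoch_window)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "StudyConfig":
        d = dict(d)
        if "latency_distribution" in d and isinstance(d["latency_distribution"], dict):
            d["latency_distribution"] = DistributionSpec.from_dict(d["latency_distribution"])
        if "magnitude_distribution" in d and isinstance(d["magnitude_distribution"], dict):
            d["magnitude_distribution"] = DistributionSpec.from_dict(d["magnitude_distribution"])
        if "epoch_window" in d:
            d["epoch_window"] = tuple(d["epoch_window"])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        d = self.to_dict()
        if path.suffix in {".yaml", ".yml"}:
            path.write_text(yaml.safe_dump(d, sort_keys=False))
        else:
            path.write_text(json.dumps(d, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "StudyConfig":
        path = Path(path)
        text = path.read_text()
        d = yaml.safe_load(text) if path.suffix in {".yaml", ".yml"} else json.loads(text)
        return cls.from_dict(d)
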