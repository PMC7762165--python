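"""Synthetic radius and release series with the study's sampling structure.

The emulated experiment observes a swelling hydrogel disc (initial radius
5 mm) on an hourly cadence; the default grid is 13 hourly points over 12 h,
which places a critical time of 7200 s exactly on the grid.  Measurement
error is additive Gaussian — the simplest defensible stand-in, since no
error model accompanies the experimental protocol — and noised release
values are truncated back into [0, 1] (truncation never alters a noiseless
value).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import logistic_radius, release_one_phase, release_two_phase
from .params import OnePhaseParams, ReleaseParams, SeriesConfig, SwellingParams, TwoPhaseParams
from .timeseries import TimeSeries

__all__ = ["NoiseSpec", "hourly_times", "generate_swelling_series", "generate_release_series"]

_RADIUS_FLOOR = 1e-6  # mm; keeps noised radii physically positive


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian measurement noise; identical seed, identical draw."""

    radius_sd: float = 0.0
    release_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.radius_sd < 0 or self.release_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")


def hourly_times(hours: int = 12) -> np.ndarray:
    """``hours + 1`` hourly sample times starting at t = 0 (seconds)."""
    return np.arange(hours + 1) * 3600.0


def _check_times(times) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("times must be non-empty")
    if times[0] < 0 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be non-negative and strictly increasing")
    return times


def generate_swelling_series(sw: SwellingParams, times=None,
                             noise: NoiseSpec = NoiseSpec()) -> TimeSeries:
    """Sample the logistic boundary with additive radius noise."""
    times = _check_times(times if times is not None else hourly_times())
    x = np.asarray(logistic_radius(times, sw), dtype=float)
    if noise.radius_sd > 0:
        rng = np.random.default_rng(noise.seed)
        x = x + rng.normal(0.0, noise.radius_sd, size=x.shape)
        x = np.maximum(x, _RADIUS_FLOOR)
    return TimeSeries(times=times, values=x, kind="radius")


def generate_release_series(sw: SwellingParams, p: ReleaseParams, times=None,
                            noise: NoiseSpec = NoiseSpec(),
                            cfg: SeriesConfig = SeriesConfig()) -> TimeSeries:
    """Sample the phase-appropriate release model with additive noise.

    The underlying model values are monotone in time; only the added noise
    can break monotonicity, and values are truncated to [0, 1] afterwards.
    """
    times = _check_times(times if times is not None else hourly_times())
    if isinstance(p, TwoPhaseParams):
        r = np.asarray(release_two_phase(times, sw, p, cfg), dtype=float)
    else:
        r = np.asarray(release_one_phase(times, sw, p, cfg), dtype=float)
    if noise.release_sd > 0:
        rng = np.random.default_rng(noise.seed)
        r = np.clip(r + rng.normal(0.0, noise.release_sd, size=r.shape), 0.0, 1.0)
    return TimeSeries(times=times, values=r, kind="release")
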