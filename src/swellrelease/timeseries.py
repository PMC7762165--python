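"""Ordered (time, value) observation containers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TimeSeries"]

_KINDS = ("radius", "release")


@dataclass
class TimeSeries:
    """A measured or simulated series of a single quantity.

    Times are in seconds and strictly increasing.  ``kind`` declares the
    measured quantity: ``"radius"`` (device radius, mm, > 0) or
    ``"release"`` (cumulative fractional release, dimensionless in [0, 1]).
    """

    times: np.ndarray
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if self.times.ndim != 1 or self.values.ndim != 1:
            raise ValueError("times and values must be one-dimensional")
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have the same length")
        if self.times.size and self.times[0] < 0:
            raise ValueError("times must be non-negative")
        if np.any(np.diff(self.times) <= 0):
            bad = int(np.flatnonzero(np.diff(self.times) <= 0)[0]) + 1
            raise ValueError(f"times must be strictly increasing (violated at index {bad})")
        if self.kind == "release":
            if np.any((self.values < 0) | (self.values > 1)):
                raise ValueError("release values must lie in [0, 1]")
        else:
            if np.any(self.values <= 0):
                raise ValueError("radius values must be > 0")

    @property
    def n_points(self) -> int:
        return int(self.times.size)

    def __len__(self) -> int:
        return self.n_points
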