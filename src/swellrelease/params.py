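"""Parameter containers for the swelling-device release models.

All quantities are carried internally in a single unit system: seconds,
millimetres, mm^2/s for diffusion coefficients and 1/s for the growth
parameter.  Unit conversion happens only at the I/O layer
(:mod:`swellrelease.io`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

__all__ = [
    "SwellingParams",
    "OnePhaseParams",
    "TwoPhaseParams",
    "ReleaseParams",
    "SeriesConfig",
]


@dataclass(frozen=True)
class SwellingParams:
    """Geometry and growth of the device boundary.

    The boundary follows the logistic law
    ``X(t) = L e^{gt} / (1 + (e^{gt} - 1)/m)``: it starts at the initial
    half-length ``L`` and saturates at ``m * L``.

    Parameters
    ----------
    L
        Initial device half-length/radius in mm (> 0).
    m
        Asymptotic swelling ratio ``lim X(t)/L`` (dimensionless, >= 1).
        ``m = 1`` means a stationary boundary.
    g
        Logistic growth parameter in 1/s (>= 0).  ``g = 0`` means a
        stationary boundary.
    """

    L: float
    m: float
    g: float

    def __post_init__(self) -> None:
        if not self.L > 0:
            raise ValueError(f"initial half-length L must be > 0, got {self.L}")
        if not self.m >= 1:
            raise ValueError(f"swelling ratio m must be >= 1, got {self.m}")
        if not self.g >= 0:
            raise ValueError(f"growth parameter g must be >= 0, got {self.g}")

    @property
    def stationary(self) -> bool:
        """True when the boundary never moves (``m = 1`` or ``g = 0``)."""
        return self.m == 1.0 or self.g == 0.0


@dataclass(frozen=True)
class OnePhaseParams:
    """Single constant effective diffusion coefficient ``D`` (mm^2/s, > 0)."""

    D: float

    def __post_init__(self) -> None:
        if not self.D > 0:
            raise ValueError(f"diffusion coefficient D must be > 0, got {self.D}")


@dataclass(frozen=True)
class TwoPhaseParams:
    """Piecewise-constant diffusion schedule with a critical time.

    The effective diffusion coefficient is ``D0`` for ``t < tc`` and ``D1``
    for ``t >= tc``.  No ordering between ``D0`` and ``D1`` is required;
    for swelling hydrogels ``D0 < D1`` is the typical observation (pores
    enlarge as the device swells) but the model itself is agnostic.
    """

    D0: float
    D1: float
    tc: float

    def __post_init__(self) -> None:
        if not self.D0 > 0:
            raise ValueError(f"first-phase D0 must be > 0, got {self.D0}")
        if not self.D1 > 0:
            raise ValueError(f"second-phase D1 must be > 0, got {self.D1}")
        if not self.tc > 0:
            raise ValueError(f"critical time tc must be > 0, got {self.tc}")


ReleaseParams = Union[OnePhaseParams, TwoPhaseParams]


@dataclass(frozen=True)
class SeriesConfig:
    """Truncation control for the Fourier release/concentration series.

    Summation stops once the current term's magnitude drops below
    ``tail_tol`` times the accumulated sum, or after ``max_terms`` terms.
    The defaults are ample for any time strictly after release starts; at
    ``t = 0`` the series converges only algebraically and the closed-form
    value is used instead.
    """

    max_terms: int = 200
    tail_tol: float = 1e-12

    def __post_init__(self) -> None:
        if self.max_terms < 1:
            raise ValueError("max_terms must be >= 1")
        if not self.tail_tol > 0:
            raise ValueError("tail_tol must be > 0")
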