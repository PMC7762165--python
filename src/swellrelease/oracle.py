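"""Finite-difference oracle for the Landau-transformed release problem.

Solves

    dc/dt = (D(t) / X(t)^2) d^2c/dzeta^2 - (Xdot/X) c,   0 < zeta < 1,

with a ghost-node Neumann condition at ``zeta = 0``, a Dirichlet sink at
``zeta = 1`` and constant initial concentration ``c0``.  The solver is a
deliberately independent route to the release curve: it never touches the
closed-form series of :mod:`swellrelease.models`, so agreement between the
two is a genuine cross-check (and settles typographic ambiguities in the
series exponents).

Time stepping is implicit trapezoidal (Crank–Nicolson) with a Rannacher
start-up — the first steps of each diffusion segment are taken as pairs of
backward-Euler half-steps — which damps the oscillation seeded by the
incompatible corner (``c0`` against the sink at ``zeta = 1``) while keeping
global second-order accuracy.  For a two-phase schedule the march splits
exactly at ``tc`` so the coefficient switch is never straddled; the state
is carried across continuously (the concentration-continuity condition).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_banded

from .models import ConcentrationField, logistic_radius, relative_growth_rate
from .params import ReleaseParams, SwellingParams, TwoPhaseParams
from .timeseries import TimeSeries

__all__ = ["OracleGrid", "solve_transformed", "release_from_field"]


@dataclass(frozen=True)
class OracleGrid:
    """Discretisation control for the finite-difference oracle.

    ``dt = None`` chooses ``t_end / 20000``.  ``n_store`` bounds the number
    of stored snapshots (taken at step times, so no temporal interpolation
    ever happens).
    """

    n_zeta: int = 401
    dt: float | None = None
    crank_nicolson: bool = True
    n_store: int = 201

    def __post_init__(self) -> None:
        if self.n_zeta < 11:
            raise ValueError("n_zeta must be >= 11")
        if self.dt is not None and not self.dt > 0:
            raise ValueError("dt must be > 0")
        if self.n_store < 2:
            raise ValueError("n_store must be >= 2")


def _second_difference(c: np.ndarray, h: float) -> np.ndarray:
    """d^2c/dzeta^2 on the interior+midplane nodes (ghost Neumann at 0,
    zero Dirichlet neighbour beyond the last node)."""
    d2 = np.empty_like(c)
    d2[0] = 2.0 * (c[1] - c[0])
    d2[1:-1] = c[:-2] - 2.0 * c[1:-1] + c[2:]
    d2[-1] = c[-2] - 2.0 * c[-1]
    return d2 / (h * h)


def _theta_step(c: np.ndarray, t0: float, dt: float, theta: float,
                D: float, sw: SwellingParams, h: float) -> np.ndarray:
    """One theta-method step from t0 to t0+dt (theta=1/2 CN, theta=1 BE)."""
    m = c.size
    a0 = D / float(logistic_radius(t0, sw)) ** 2
    b0 = float(relative_growth_rate(t0, sw))
    a1 = D / float(logistic_radius(t0 + dt, sw)) ** 2
    b1 = float(relative_growth_rate(t0 + dt, sw))

    rhs = c.copy()
    if theta < 1.0:
        rhs += (1.0 - theta) * dt * (a0 * _second_difference(c, h) - b0 * c)

    r = theta * dt * a1 / (h * h)
    ab = np.zeros((3, m))
    ab[0, 1:] = -r                      # super-diagonal
    ab[0, 1] = -2.0 * r                 # ghost-node Neumann row
    ab[1, :] = 1.0 + 2.0 * r + theta * dt * b1
    ab[2, :-1] = -r                     # sub-diagonal
    return solve_banded((1, 1), ab, rhs)


def solve_transformed(sw: SwellingParams, p: ReleaseParams, c0: float,
                      grid: OracleGrid, t_end: float) -> ConcentrationField:
    """Integrate the transformed problem to ``t_end`` and return the field.

    The returned field includes the boundary node ``zeta = 1`` (identically
    zero for ``t > 0``) and the boundary trajectory ``X(t)`` at each stored
    time.  Raises ``RuntimeError`` with a refinement hint if the solution
    loses finiteness (should not occur for the implicit schemes used).
    """
    if not t_end > 0:
        raise ValueError("t_end must be > 0")
    if isinstance(p, TwoPhaseParams) and p.tc < t_end:
        segments = [(0.0, p.tc, p.D0), (p.tc, t_end, p.D1)]
    elif isinstance(p, TwoPhaseParams):
        segments = [(0.0, t_end, p.D0)]
    else:
        segments = [(0.0, t_end, p.D)]

    dt0 = grid.dt if grid.dt is not None else t_end / 20000.0
    h = 1.0 / (grid.n_zeta - 1)
    zeta = np.linspace(0.0, 1.0, grid.n_zeta)
    c = np.full(grid.n_zeta - 1, float(c0))  # unknowns: all nodes except zeta=1

    total_steps = sum(max(1, int(np.ceil((b - a) / dt0))) for a, b, _ in segments)
    stride = max(1, total_steps // (grid.n_store - 1))

    times = [0.0]
    snaps = [np.concatenate([c, [0.0]])]  # sink applies for t>0; initial surface value kept 0
    snaps[0][-1] = float(c0)              # t=0 snapshot shows the unreleased state
    step_count = 0
    for seg_start, seg_end, D in segments:
        n_steps = max(1, int(np.ceil((seg_end - seg_start) / dt0)))
        dt = (seg_end - seg_start) / n_steps
        t = seg_start
        for i in range(n_steps):
            if grid.crank_nicolson and i < 2 and seg_start == 0.0:
                # Rannacher start-up: two BE half-steps replace the CN step.
                # Only the initial corner (c0 against the sink) is rough; the
                # state at tc is smooth, so the coefficient switch needs no
                # smoothing and D0=D1 stays an exact no-op.
                c = _theta_step(c, t, dt / 2.0, 1.0, D, sw, h)
                c = _theta_step(c, t + dt / 2.0, dt / 2.0, 1.0, D, sw, h)
            else:
                theta = 0.5 if grid.crank_nicolson else 1.0
                c = _theta_step(c, t, dt, theta, D, sw, h)
            t = seg_start + (i + 1) * dt
            step_count += 1
            if step_count % stride == 0 or i == n_steps - 1:
                if not np.all(np.isfinite(c)):
                    raise RuntimeError(
                        "oracle solution lost finiteness; refine the grid "
                        f"(n_zeta={grid.n_zeta}, dt={dt:.3g})")
                if times[-1] != t:
                    times.append(t)
                    snaps.append(np.concatenate([c, [0.0]]))

    times_arr = np.asarray(times)
    return ConcentrationField(
        zeta_grid=zeta,
        times=times_arr,
        c=np.vstack(snaps),
        c0=float(c0),
        X_of_t=np.asarray(logistic_radius(times_arr, sw), dtype=float),
    )


def release_from_field(field: ConcentrationField, sw: SwellingParams) -> TimeSeries:
    """Fractional release ``R(t) = 1 - X(t)/(L c0) * int_0^1 c dzeta``.

    The integral is a composite trapezoid over the stored grid; values are
    snapped to [0, 1] only when within quadrature tolerance of the bounds.
    """
    integral = np.trapezoid(field.c, field.zeta_grid, axis=1)
    r = 1.0 - field.X_of_t / (sw.L * field.c0) * integral
    tol = 1e-6
    r[(r < 0) & (r > -tol)] = 0.0
    r[(r > 1) & (r < 1 + tol)] = 1.0
    # exact zero at t=0 is a modelling convention; enforce for the stored IC
    if field.times[0] == 0.0:
        r[0] = 0.0
    return TimeSeries(times=field.times, values=r, kind="release")
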