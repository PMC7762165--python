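"""Two-stage least-squares estimation of swelling and release parameters.

Stage 1 fits the logistic growth parameter ``g`` to the radius series.
Stage 2 fits the diffusion schedule to the release series, either a single
coefficient ``D`` (one-phase) or ``(D0, D1, tc)`` (two-phase).  The
critical time is not optimised continuously: following the estimation
algorithm, each interior observation time is tried as a candidate ``tc``,
the bounded two-parameter least-squares problem in ``(D0, D1)`` is solved
for each, and the candidate with the smallest error wins (ties broken
towards the earliest candidate).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .models import inverse_square_integral, logistic_radius, release_one_phase, release_two_phase
from .params import OnePhaseParams, SeriesConfig, SwellingParams, TwoPhaseParams
from .timeseries import TimeSeries

__all__ = ["FitResult", "fit_growth", "fit_one_phase", "fit_two_phase"]

D_BOUNDS = (1e-12, 1.0)  # mm^2/s search interval for diffusion coefficients
_MULTISTART = (0.1, 1.0, 10.0)


@dataclass
class FitResult:
    """Outcome of a least-squares fit.

    ``sse`` is the plain (unweighted) sum of squared residuals at the
    returned parameters; for two-phase fits it is the minimum over the
    ``tc`` candidate grid and ``candidates`` keeps the whole per-candidate
    table for diagnostics.
    """

    params: Union[SwellingParams, OnePhaseParams, TwoPhaseParams]
    sse: float
    n_obs: int
    converged: bool = True
    degenerate: bool = False
    message: str = ""
    candidates: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if self.sse < 0:
            raise ValueError("sse must be >= 0")


def _tight_ls(fun, x0, bounds, x_scale):
    return least_squares(fun, x0, bounds=bounds, x_scale=x_scale,
                         xtol=1e-15, ftol=1e-15, gtol=1e-15)


def fit_growth(ts: TimeSeries, L: float | None = None, m: float | None = None,
               joint: bool = False) -> FitResult:
    """Fit the logistic growth parameter ``g`` to a radius series.

    ``L`` defaults to the first observed radius and ``m`` to
    ``max(radius)/L``; only ``g`` is optimised unless ``joint=True``, in
    which case ``(L, m, g)`` are fitted together (useful for noisy data
    where the first/max observations are poor anchors).

    A constant radius series is degenerate — the objective is independent
    of ``g`` — and returns ``g = 0`` with ``degenerate=True`` rather than
    an arbitrary minimiser.
    """
    if ts.kind != "radius":
        raise ValueError("fit_growth expects a radius series")
    if ts.n_points < 3:
        raise ValueError("need at least 3 observations to fit growth")
    t, x = ts.times, ts.values
    L0 = float(L) if L is not None else float(x[0])
    m0 = float(m) if m is not None else max(float(np.max(x)) / L0, 1.0)

    if np.ptp(x) == 0.0 or m0 == 1.0:
        sw = SwellingParams(L=L0, m=m0, g=0.0)
        sse = float(np.sum((x - logistic_radius(t, sw)) ** 2))
        return FitResult(params=sw, sse=sse, n_obs=ts.n_points, degenerate=True,
                         message="constant radius: error independent of g; returning g=0")

    def resid_g(g_vec):
        return x - logistic_radius(t, SwellingParams(L=L0, m=m0, g=float(g_vec[0])))

    # coarse log-grid bracket, then a tight bounded refinement
    grid = np.concatenate([[0.0], np.logspace(-8, -1, 57)])
    sses = [float(np.sum(resid_g([g]) ** 2)) for g in grid]
    g_start = float(grid[int(np.argmin(sses))])
    if g_start == 0.0:
        g_start = 1e-8
    sol = _tight_ls(resid_g, [g_start], ([0.0], [1.0]), [max(g_start, 1e-8)])
    g_hat = float(sol.x[0])

    if joint:
        def resid_joint(p):
            Lj, mj, gj = p
            return x - logistic_radius(t, SwellingParams(L=Lj, m=max(mj, 1.0), g=gj))
        sol = _tight_ls(resid_joint, [L0, max(m0, 1.0 + 1e-6), g_hat],
                        ([1e-9, 1.0, 0.0], [np.inf, np.inf, 1.0]),
                        [max(L0, 1e-3), max(m0, 1.0), max(g_hat, 1e-8)])
        L0, m0, g_hat = float(sol.x[0]), float(max(sol.x[1], 1.0)), float(sol.x[2])

    sw = SwellingParams(L=L0, m=m0, g=g_hat)
    sse = float(np.sum((x - logistic_radius(t, sw)) ** 2))
    return FitResult(params=sw, sse=sse, n_obs=ts.n_points, converged=bool(sol.success))


def _initial_d(ts: TimeSeries, sw: SwellingParams) -> float:
    """Heuristic ``D`` from the mid-release observation via the classical
    slab leading term (short-time square-root law below R ~ 0.2)."""
    t, r = ts.times, ts.values
    usable = (t > 0) & (r > 0) & (r < 1)
    if not usable.any():
        return 1e-4
    idx = np.flatnonzero(usable)
    mid = idx[int(np.argmin(np.abs(r[idx] - 0.5)))]
    R = float(r[mid])
    if R >= 0.2:
        w = -(4.0 / np.pi**2) * np.log(np.pi**2 * (1.0 - R) / 8.0)
    else:
        w = np.pi * R * R / 4.0
    I = float(inverse_square_integral(0.0, float(t[mid]), sw))
    if I <= 0 or w <= 0:
        return 1e-4
    return float(np.clip(w / I, *D_BOUNDS))


def fit_one_phase(ts: TimeSeries, sw: SwellingParams,
                  cfg: SeriesConfig = SeriesConfig()) -> FitResult:
    """Fit the single diffusion coefficient ``D`` of the one-phase model.

    Bounded search on ``D in [1e-12, 1]`` mm^2/s with a three-point
    multistart (x0.1, x1, x10) around a slab-approximation heuristic.
    An identically-zero release series pins ``D`` at the lower bound and
    warns.
    """
    if ts.kind != "release":
        raise ValueError("fit_one_phase expects a release series")
    if ts.n_points < 3:
        raise ValueError("need at least 3 observations to fit release")
    t, r = ts.times, ts.values

    if np.all(r == 0.0):
        warnings.warn("all-zero release series: D pinned at the lower search bound")
        p = OnePhaseParams(D=D_BOUNDS[0])
        sse = float(np.sum((r - release_one_phase(t, sw, p, cfg)) ** 2))
        return FitResult(params=p, sse=sse, n_obs=ts.n_points, degenerate=True,
                         message="all-zero release: D at lower bound")

    def resid(d_vec):
        return r - release_one_phase(t, sw, OnePhaseParams(D=float(d_vec[0])), cfg)

    d0 = _initial_d(ts, sw)
    best = None
    for f in _MULTISTART:
        start = float(np.clip(d0 * f, *D_BOUNDS))
        sol = _tight_ls(resid, [start], ([D_BOUNDS[0]], [D_BOUNDS[1]]), [start])
        if best is None or sol.cost < best.cost:
            best = sol
    p = OnePhaseParams(D=float(best.x[0]))
    sse = float(np.sum(resid(best.x) ** 2))
    return FitResult(params=p, sse=sse, n_obs=ts.n_points, converged=bool(best.success))


def fit_two_phase(ts: TimeSeries, sw: SwellingParams,
                  cfg: SeriesConfig = SeriesConfig()) -> FitResult:
    """Fit ``(D0, D1, tc)`` of the two-phase model by candidate-grid search.

    Candidate critical times are the interior observation times with at
    least two observations strictly on each side; for each candidate the
    bounded problem in ``(D0, D1)`` is solved over the full residual vector
    (early points through the first-phase branch, later points through the
    second).  The winner is the candidate with minimal error; exact ties go
    to the smaller ``tc``.  The per-candidate table is kept in
    ``FitResult.candidates``.
    """
    if ts.kind != "release":
        raise ValueError("fit_two_phase expects a release series")
    if ts.n_points < 5:
        raise ValueError("need at least 5 observations to fit a two-phase model")
    t, r = ts.times, ts.values

    candidates = [float(tk) for tk in t
                  if (t < tk).sum() >= 2 and (t > tk).sum() >= 2 and tk > 0]
    if not candidates:
        raise ValueError("no admissible tc candidates (need >=2 points strictly in each phase)")

    d_heur = _initial_d(ts, sw)
    rows = []
    for tc in candidates:
        def resid(d_vec, tc=tc):
            p = TwoPhaseParams(D0=float(d_vec[0]), D1=float(d_vec[1]), tc=tc)
            return r - release_two_phase(t, sw, p, cfg)

        best = None
        for f in _MULTISTART:
            start = float(np.clip(d_heur * f, *D_BOUNDS))
            sol = _tight_ls(resid, [start, start],
                            ([D_BOUNDS[0]] * 2, [D_BOUNDS[1]] * 2), [start, start])
            if best is None or sol.cost < best.cost:
                best = sol
        rows.append({"tc": tc, "D0": float(best.x[0]), "D1": float(best.x[1]),
                     "sse": float(np.sum(resid(best.x) ** 2)),
                     "n_phase1": int((t <= tc).sum()), "n_phase2": int((t > tc).sum()),
                     "converged": bool(best.success)})

    table = pd.DataFrame(rows).sort_values("tc", ignore_index=True)
    winner = table.loc[table["sse"].idxmin()]  # idxmin takes the first minimum: earliest tc
    p = TwoPhaseParams(D0=float(winner["D0"]), D1=float(winner["D1"]), tc=float(winner["tc"]))
    sse = float(np.sum((r - release_two_phase(t, sw, p, cfg)) ** 2))
    return FitResult(params=p, sse=sse, n_obs=ts.n_points,
                     converged=bool(winner["converged"]), candidates=table)
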