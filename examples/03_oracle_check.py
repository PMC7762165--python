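"""Cross-check the closed-form series against the finite-difference solver.

The Crank-Nicolson oracle integrates the Landau-transformed moving-boundary
problem directly, never touching the Fourier series, so the sup-norm gap
between the two release curves measures the correctness of both routes.
"""

import numpy as np

from swellrelease import (
    OracleGrid,
    SwellingParams,
    TwoPhaseParams,
    release_from_field,
    release_two_phase,
    solve_transformed,
)

sw = SwellingParams(L=5.0, m=2.0, g=1.17298e-4)
p = TwoPhaseParams(D0=3.25908e-4, D1=1.49489e-3, tc=7200.0)

field = solve_transformed(sw, p, c0=1.0, grid=OracleGrid(), t_end=43200.0)
oracle = release_from_field(field, sw)
series = release_two_phase(oracle.times, sw, p)

sup = float(np.max(np.abs(series - oracle.values)))
print(f"stored time points:            {oracle.times.size}")
print(f"series-vs-oracle sup error:    {sup:.3e}")
print(f"release at 12 h (series):      {series[-1]:.6f}")
print(f"release at 12 h (oracle):      {oracle.values[-1]:.6f}")
print("\nA gap below 1e-3 at the default grid (401 spatial nodes) confirms the")
print("series solution, including the eigenvalues lambda_n = (2n+1)*pi/2.")
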