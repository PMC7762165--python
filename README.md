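# swellrelease

Release-kinetics modelling for **swelling drug-delivery devices** — hydrogel
discs and similar matrices whose boundary grows as they absorb fluid,
enlarging pores and accelerating drug diffusion.  The package is aimed at
pharmaceutics researchers who measure device radius and cumulative drug
release on an hourly cadence in vitro and want mechanistic parameters
(growth rate, effective diffusivities, the changeover time between the
pre-swollen and swollen regimes) out of those curves.

## The model

Drug transport in a uniformly swelling 1-D device `0 ≤ x ≤ X(t)` with a
no-flux midplane and a perfect-sink surface follows an advection–diffusion
equation.  The Landau substitution `ζ = x/X(t)` maps it onto the fixed
interval `[0, 1]`:

```
∂c/∂t = (D/X²) ∂²c/∂ζ² − (Ẋ/X) c,    c(ζ,0)=c₀,  ∂c/∂ζ(0,t)=0,  c(1,t)=0
```

The boundary grows logistically, `X(t) = L e^{gt} / (1 + (e^{gt}−1)/m)`,
from the initial radius `L` to the swollen asymptote `mL` at rate `g`.
Separation of variables gives eigenvalues `λₙ = (2n+1)π/2` and the
cumulative fractional release

```
R(t) = 1 − Σₙ 8/((2n+1)²π²) · exp(−λₙ² W(t)),
W(t) = D ∫₀ᵗ X(t')⁻² dt'          (one phase)
W(t) = D₀ I(0, min(t,t_c)) + D₁ I(t_c, t)   (two phases)
```

where the boundary integral `I` has an elementary closed form for logistic
growth.  The **two-phase model** acknowledges that the effective
diffusivity of a swelling network is not constant: a slower `D₀` before
the critical time `t_c` (dense, pre-swollen) and a faster `D₁` after it
(enlarged pores), joined by concentration continuity so the release curve
is continuous.

Estimation is two-stage least squares: fit `g` to the radius series, then
for each interior observation time taken as a candidate `t_c`, solve the
bounded problem in `(D₀, D₁)` and keep the candidate with the smallest sum
of squared residuals.

An independent Crank–Nicolson finite-difference solver for the transformed
PDE acts as an oracle: it validates the series (including the eigenvalue
normalisation) to ~1e-5 sup-norm at its default grid, with second-order
grid convergence.

## Worked example

Fitting noisy synthetic hourly data (13 points over 12 h, radius noise
0.05 mm, release noise 0.01) generated from known kinetics
(`examples/02_fit_two_phase.py`):

```
parameter          true    recovered
g (1/s)     1.17298e-04  1.17641e-04
D0 mm2/s    3.25908e-04  3.39057e-04
D1 mm2/s    1.49489e-03  1.46823e-03
tc (s)             7200         7200

least-squares error at the optimum: 1.012e-03
```

The growth rate comes back within 0.3%, the diffusivities within a few
percent, and the critical time is recovered exactly (it sits on the
sampling grid, and the candidate search tries every interior observation
time).  The per-candidate error table printed below it shows the error
minimum clearly isolated at `tc = 7200 s`.

The other examples evaluate the release curves (`01_release_curves.py`),
cross-check the series against the PDE oracle (`03_oracle_check.py`,
sup-norm gap 7.7e-6) and compute the per-phase release-rate diagnostic
(`04_phase_rates.py`).

## Command line

The same workflows are exposed as a thin CLI:

```bash
swellrelease simulate --out data/                    # synthetic radius+release CSVs
swellrelease fit-growth --data data/radius.csv
swellrelease fit-release --data data/release.csv --model two --table
swellrelease oracle-check
swellrelease evaluate --model two --plot curve.png
```

CSV files are two columns (`time,value`) with an optional
`# units: time=h length=mm` comment; reports are JSON.

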