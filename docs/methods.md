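# Methods

## Physical model and assumptions

The device is a drug-loaded polymer matrix (the motivating system is a
1-cm bacterial-cellulose hydrogel disc loaded with a model protein) that
swells while it releases.  The model makes the following assumptions:

- Transport and swelling are one-dimensional and uniform: the slab
  solution on `0 ≤ x ≤ X(t)` is applied along the disc radius, with a
  no-flux condition at the centre and a perfect sink at the surface.
  Cylindrical (Bessel-mode) corrections are out of scope.
- The boundary grows logistically, `X(t) = L e^{gt}/(1 + (e^{gt}−1)/m)`;
  `L` (mm) is the initial radius, `m ≥ 1` the asymptotic swelling ratio,
  `g ≥ 0` (1/s) the growth rate.  `m = 1` or `g = 0` gives a stationary
  boundary and the model collapses to the classical plane-sheet solution.
- The effective diffusivity is piecewise constant: a single `D` (one
  phase) or `D₀` before and `D₁` after a critical time `t_c`, joined by
  concentration continuity.  A genuinely time-continuous `D(t)` is not
  modelled, nor is polymer degradation or a non-sink medium.
- Initial concentration is uniform (`c₀`); release starts at `t = 0` in a
  single medium.

Under the Landau map `ζ = x/X(t)` the advection term drops out and the
problem separates with eigenfunctions `cos((2n+1)πζ/2)`, hence
`λₙ = (2n+1)π/2`.  Every series exponent is `λₙ² W(t)` with the
diffusion-weighted boundary integral

```
W(t) = D ∫₀ᵗ X⁻² dt'                         (one phase)
W(t) = D₀ I(0, t_c) + D₁ I(t_c, t)            (t > t_c)
```

`I(t₁,t₂) = ∫ X⁻² dt` has a closed form for logistic growth; it is
evaluated through `expm1` of the interval so that interval additivity
holds to ~1e-12 relative even for short intervals, and the stationary
limit `(t₂−t₁)/L²` is taken analytically rather than through small-`g`
arithmetic.  The boundary law itself is computed as
`X = mL/(1 + (m−1)e^{−gt})`, which is overflow-free for any `gt`.

## Numerical choices

**Series truncation.**  Summation stops when the current term falls below
`tail_tol` (default 1e-12) times the accumulated sum, capped at
`max_terms` (default 200).  For any `t > 0` in realistic regimes the
exponential factor makes ≤200 terms ample.  At `t = 0` the release is
defined as exactly 0 (the identity `Σ 8/((2n+1)²π²) = 1` converges only
algebraically); the concentration profile at `t = 0` is the truncated
Fourier reconstruction of the constant `c₀`, with the inherent Gibbs
oscillation near `ζ = 1`.

**Floating-point saturation.**  Mathematically `0 ≤ R < 1` strictly; in
double precision, once `W ≳ 15` the surviving term `e^{−λ₀²W}` drops
below the spacing of numbers near 1 and `R` rounds to exactly 1.0.
Property tests therefore exercise device-scale geometries
(`L ∈ [4, 20] mm`) where the gap is representable.

**Estimation.**  Stage 1 minimises `Σ (X̄ᵢ − X(tᵢ; g))²` over `g` alone,
with `L` anchored to the first observation and `m` to `max/first` by
default; both can be fixed explicitly, and a joint `(L, m, g)` fit is
available behind a flag for noisy data.  Note that on a finite window the
default `m` anchor underestimates the asymptote (e.g. a 12-hour window at
`g ≈ 1.2e-4` ends at `X = 9.94` of an `mL = 10` asymptote), which biases
`g` by a few percent; when the geometry is known, pass it.  The solver is
a bounded trust-region least-squares refinement seeded by a coarse
logarithmic grid in `g`.  A constant radius series makes the objective
independent of `g` and is returned as `g = 0` with a degeneracy flag.

Stage 2 searches `D ∈ [1e-12, 1] mm²/s` (one phase) or `(D₀, D₁)` in the
same box (two phases) with a three-point multistart (×0.1, ×1, ×10)
around a plane-sheet heuristic inverted from the observation nearest
mid-release.  Candidate critical times are the interior observation times
with at least two observations strictly on each side — the changeover is
deliberately not optimised continuously, matching the estimation
algorithm's grid-over-observations design; exact ties go to the earliest
candidate.  Residuals are plain (unweighted) sums of squares.  The
reported error is recomputed from the returned parameters, so it is
self-consistent by construction.

**Finite-difference oracle.**  An independent check of the closed forms:
implicit trapezoidal (Crank–Nicolson) stepping of the transformed PDE on
a uniform `ζ` grid (default 401 nodes, `dt = t_end/20000`), ghost-node
Neumann at `ζ = 0` (second order — one-sided differencing would pollute
the convergence-order measurement), Dirichlet at `ζ = 1`, and the
reaction coefficient `Ẋ/X = g(1 − X/(mL))` evaluated analytically.  The
march splits exactly at `t_c`, carrying the state across continuously.
The first two steps from `t = 0` are taken as backward-Euler half-step
pairs (Rannacher smoothing) to damp the oscillation seeded by the
incompatible corner `c₀ vs c(1)=0`; the restart at `t_c` is smooth and is
*not* smoothed, which keeps the `D₀ = D₁` schedule bit-comparable to a
single-phase solve.  Release is recovered from the field by composite
trapezoid, consistent at second order.  Observed behaviour at the default
grid: sup-norm gap to the series ≈ 1e-5, spatial convergence order ≈ 2.05.

## Synthetic data

The generator emulates the study conditions: 13 hourly observations over
12 h (which puts `t_c = 7200 s` on the sampling grid) of a disc with
initial radius 5 mm and assumed swelling ratio 2, with additive Gaussian
noise on both channels and the release channel truncated back into
[0, 1].  Gaussian noise is a choice of convenience — the in-vitro
protocol reports no error model — and truncation (rather than re-drawing)
is documented behaviour; truncation never alters a noiseless value.  What
passing recovery tests show is therefore identifiability under idealised
iid noise at the experiment's cadence; they do not speak to serially
correlated assay error, evaporation/medium-exchange artefacts, the
early acidic-medium hold-up of the real protocol, or model misfit in `X(t)`.

Reference kinetics used throughout the tests and examples
(`g = 1.17298e-4 1/s`, `D = 8.58865e-4`, `D₀ = 3.25908e-4`,
`D₁ = 1.49489e-3 mm²/s`, `t_c = 7200 s`) describe a moderately swelling
formulation whose second-phase diffusivity is ≈4.6× the first; `L = 5 mm`
and `m = 2` are declared synthetic values, as the fitted geometry of the
motivating devices is not published numerically.

## The phase-rate diagnostic

`phase_release_rate` reports the secant slope `ΔR/Δt` over each phase
(first→last observation within the phase); the step size of a pointwise
difference quotient is unspecified in general, so the whole-phase secant
is the package's convention.  The direction `rate₁ < rate₂` is implied by
`D₀ ≪ D₁` only while diffusivity dominates: the second-phase secant spans
the long tail of the experiment, and once release saturates it flattens
below the first-phase slope even for `D₁ > D₀` (observed already at the
reference contrast of 4.6×).  A fast-swelling, heavily loaded device can
likewise show a larger first-phase rate.  The diagnostic is therefore
directional evidence, not an estimator of the diffusivity ordering.

## Known limitations

- Planar (slab) geometry applied radially; no cylindrical or 3-D solution.
- Exactly two diffusion phases; the candidate grid for `t_c` is limited to
  observation times, so `t_c` resolution equals the sampling interval.
- No uncertainty quantification: point estimates and residual errors only.
- The default growth-fit anchors (`L` = first, `m` = max/first) are biased
  on windows that end before the swelling plateau (see above).
- Problem sizes in the test-suite oracle comparisons (spatial grids of
  101–401 nodes, 20 random parameter sets) were chosen to make the battery
  a routine desk-side run while leaving the grid-convergence order
  cleanly measurable.
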