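# Methods

This note records the model equations as implemented, the numerical
choices behind them, the role of the fixture families, and the known
limitations.  Everything here is computed by the package's tests or by
`scripts/acceptance.py`; no number is quoted that the code does not
produce.

## Model structure

The simulator is a strictly one-way cascade:

```
collagen age PDE  →  (C1, C2, F)  →  regulator/moment ODEs  →  mineral size PDE  →  mechanics
```

There is no feedback from minerals to collagen.  The collagen stage is
solved in closed form, so the only discretization error in the default
pipeline sits in the mineral PDE (which is itself redundant with the
moment ODEs and used as a cross-check) and in the adaptive ODE
integration (LSODA, `rtol=1e-8`, `atol=1e-10`).

### Collagen ageing

`c_t + c_a = 0` with `c(t,0)=0` has the exact solution
`c(t,a) = c0(a−t)` for `a ≥ t`, zero otherwise.  The implementation
shifts the grid itself rather than resampling, so the total population is
conserved to machine precision; a truncation age may be imposed, in which
case clipped mass is reported as a warning.  Pool splits insert the
threshold `α` (or `α − t`) as an explicit quadrature node, which makes
`C1/C2` exact for piecewise-linear densities; jump discontinuities are
encoded by duplicated grid nodes and contribute their left limit at a
cut.  A first-order upwind solver is included solely to demonstrate
convergence to the characteristics solution.

The maturity fraction `F(t) = C2/C` is non-decreasing and reaches 1 at
`t = α − inf supp(c0)` for compactly supported initial data.

### Regulators and plastic energy

The rate constants (0.1, 0.2, 0.012, 0.001, Hill exponent 10) are the
published calibration of the underlying compartment model and are kept
fixed; only initial values, `α` and `η` are user-facing.  Initial values
default to `I(0)=0.55`, `N(0)=0.7`, `ωp(0)=1`.

The `ωp` equation is algebraically the time derivative of the ratio law
`C1/C2 = 0.71 ωp + 1` under two-compartment maturation
(`C1' = −0.1C1`, `C2' = 0.1C1`); the test suite verifies the integrated
trajectory tracks the algebraic law to 1e−6 relative over `t ∈ [0, 50]`.
The printed initial value `ωp(0)=1` is *not* consistent with that law for
a largely mature initial matrix (`C1/C2 < 1` implies negative `ωp`); the
default honours the printed value, and `wp_init="consistent"` selects the
self-consistent initialization instead.  `ωp` is non-increasing for any
non-negative collagen trajectory since its numerator is
`−0.1 C1 C2 − 0.1 C1² ≤ 0`.

The inhibitor Hill term `I¹⁰` is computed in log space above `I = 10³`
to avoid overflow; denominators are bounded below by `b = 0.001`.

### Kinetic laws

```
V(s) = s⁵⁰ · exp(−0.5 (s + 1/3)²)               growth speed
k(N,I,s) = [10N/(1+I²)] · s · exp(−10s² + s)    aggregation kernel
m(t,0) = 0.001 N/(0.001 + I¹⁰) · exp(−ηM)       precipitation influx
```

with defaults `α = 3` (maturation threshold) and `η = 0.2` (precipitation
damping).  Two details deserve note:

* The source formulas circulate in typographically flattened form, and
  the exponent grouping is genuinely ambiguous.  The defaults above are
  the most plausible readings; `KineticParameters.v_variant` /
  `k_variant` expose the alternate readings (`(s+13)²` grouping;
  `exp(−10s²)+s` split) so qualitative comparisons can be run under each.
* The modelling narrative asks for `V(1) = 0` (growth stops at full
  maturity) but the printed function gives `V(1) = e^{−8/9} ≈ 0.411`.
  The function is implemented exactly as printed; consequently, once
  `F = 1` is reached the mineral mass `P` grows without bound and the
  mean crystal size does not plateau.  This is why the demonstration
  scenario (below) keeps `F < 1` over its window.

### Mineral population

The size-structured equation is solved on a uniform grid over
`[0, x_max]` with:

* first-order upwind advection (`V ≥ 0` makes it stable and
  sign-correct), with the precipitation density imposed as the inflow
  ghost value at size zero and free outflow at `x_max`;
* the coagulation gain `∫₀ˣ m(x−y)m(y) dy` as a discrete
  autoconvolution with trapezoid end corrections — its zeroth moment
  matches `M²` to quadrature accuracy (the closure identity) and its
  first moment matches `2MP` to ~1e−5, so mass is conserved by
  aggregation;
* the loss term `2 k m M` with the printed factor 2 (one-dimensional
  joining symmetry), which makes the count equation `M' = −kM²`, and the
  tests target exactly that convention;
* explicit midpoint (RK2) stepping with `Δt` from the CFL bound with
  safety 0.5, plus an aggregation time-scale bound; a caller-supplied
  `Δt` violating the bound raises with the stable step named.  Negative
  densities produced by stepping are clipped at zero and the clipped mass
  accumulated as a diagnostic (zero in all shipped scenarios).

Grid defaults: `x_max = 20` mean initial sizes and 1024 nodes.  The
first-order upwind scheme needs roughly this resolution for the
structured moments to track the reduced ODEs within 1% when growth and
influx are active; the dominant error is an `O(Δx)` mass defect at the
inflow corner when the boundary value and the local density disagree
(e.g. when growth switches on against a stale size-zero density).  For
pure-coagulation benchmarks 256 nodes are ample, but the domain must
contain the coarsening tail over the whole horizon: the constant-kernel
benchmark uses `x_max = 30` with a horizon of 1.5 so that the analytic
count decay is matched to <0.5% while mass drifts <1e−3.

### Mechanics

`ε = σ/E + β(σ/E)ⁿ` with `n, β` (and in `coupled` mode `E`) from the
polynomial microstructure maps.  The maps are only meaningful near the
`(F, M)` band the mineralization model actually visits (`F ≈ 0.8`,
`M ≈ 0.56`); outside it they can produce `n ≤ 0` or `E ≤ 0`, which is
flagged with a warning and never silently clipped.  Toughness is computed
both by trapezoid quadrature on the sampled curve and from the analytic
antiderivative

```
∫₀^{ε(σmax)} σ dε = σmax ε(σmax) − [σmax²/(2E) + βE (σmax/E)^{n+1}/(n+1)]
```

which agree to 0.1% at ≥1000 stress points (property-tested on random
valid draws).  The yield point defaults to the standard 0.2% offset,
solved by bracketed root finding on the plastic term; `yield_method =
"none"` reports the elastic share at `σ_max` instead.  The stress grid
runs to `σ_max = 120` with `E = 10` by default — the model's own
internally inconsistent unit mix, retained deliberately; outputs are
model units, not GPa/MPa, and with `σ/E = 12` the plastic branch
dominates, so printed energies of the maturation fan are large and only
their ordering (monotone increasing with maturation time) is meaningful.

### Demonstration scenario

`RunConfig.reference()` is the scenario used in the README, the
qualitative acceptance test and the acceptance script: threshold
`α = 8`, a two-component collagen profile with 60% of the population
mature and the immature 40% spread widely (triangular bump over
`[0, 8]`), horizon `t = 5`.  These choices keep `F` below ~0.92 over the
window, which is the regime where the model produces the documented
qualitative behaviour: regulators decaying to small positive plateaus
(nucleators far faster in relative terms), non-increasing plastic
energy, and a mean crystal size that rises and plateaus as aggregation
dies off.  The default config (`α = 3`, 80% mature, horizon 6) instead
drives `F` to 1 mid-run and demonstrates the growth-dominated regime.

## Fixture families

The initial distributions `c0(a)` and `m0(x)` are not experimentally
constrained, so the package ships deterministic named families instead:
collagen `uniform`, `triangular`, `two_mass` (fraction `p_mature` placed
above the threshold, so `F(0) = p_mature` by construction); mineral
`exponential`, `gaussian_bump` (an all-small-crystal state), and
`lognormal`.  Components are normalized under grid quadrature so stated
totals are exact.  These emulate plausible maturity/size profiles; they
do not capture measured distributions from any specific tissue, so
passing tests demonstrate properties of the model under controlled
initial data, not agreement with a particular bone sample.

## Degenerate inputs and tie-breaks

* Zero total collagen → maturity undefined, explicit error; a profile
  with `C2 = 0` is rejected because the `ωp` equation divides by `C2²`.
* Zero crystal count → mean size reported as NaN.
* Zero-length runs (`t_end = 0`) echo the initial state.
* Regulator levels are clamped at zero inside rate-law evaluations to
  tolerate integrator micro-overshoot; outputs are checked non-negative.

## Limitations

* No rupture criterion: curves extend to `σ_max` regardless of physical
  failure, so energies past a realistic ultimate strain are nominal.
* No feedback from mineral content to collagen kinetics, no collagen
  synthesis/degradation, no fragmentation or size-dependent kernels, and
  one-dimensional crystal geometry only.
* The Kelvin–Voigt element is provided as a stand-alone constitutive
  law (creep/relaxation closed forms); it is not composed with the
  Ramberg–Osgood curve generator.
* The problem sizes used in tests and in the acceptance script (grids of
  256–1024 size nodes, horizons of a few maturation-time units, 100-draw
  property checks) were chosen so the whole suite completes in seconds
  while leaving comfortable numerical margins.
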