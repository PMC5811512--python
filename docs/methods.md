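# Methods

## Model and assumptions

The package treats a voltage-gated, non-inactivating channel whose gating
is a linear chain of `m` equal and independent gates (Hodgkin–Huxley
convention) and whose blocker binds exclusively to the open state:

```
C_m <-> ... <-> C_1 <-> O <-> B        (n = m + 2 states)
```

From the state with `j` open gates the opening rate is `(m−j)·α` and the
closing rate `j·β`; block association is `γ = κ·L` (first order in blocker
concentration `L`) and dissociation is `δ`. All transitions are
memoryless, so the occupancy probabilities obey the master equation
`x′ = A x` with a tridiagonal generator whose columns sum to zero. Rates
are quoted in reciprocal milliseconds throughout the documentation and the
CLI; the mathematics is unit-agnostic.

Assumptions inherited from this scheme: no intrinsic inactivation, no
closed-state or trapped block, no cyclic pathways (so the spectrum is real
— the generator is similar to a symmetric matrix), and a voltage-clamp
initial condition with every channel in the most-closed state `C_m`, as
after a strongly hyperpolarized holding potential. Branched or cyclic
schemes and time-varying voltage within a single solve are out of scope.

## Exact solution and its oracles

`x(t) = Σ cᵢVᵢ e^{rᵢt}` via `numpy.linalg.eig`, with the eigenvalues
sorted descending (the single zero mode first, then the slowest
relaxation). Three independent routes to the same trajectory guard each
other in the tests:

1. the eigendecomposition reconstruction (the production path);
2. a hand-implemented scaling-and-squaring truncated-series matrix
   exponential (deliberately sharing no code with route 1; cross-checked
   in turn against `scipy.linalg.expm`);
3. the Putzer recursion, which evaluates `exp(At)` from the eigenvalues
   alone through the matrix sequence `M₁ = I`, `Mᵢ = (A − rᵢ₋₁I)Mᵢ₋₁` and
   the closed-form cascade solutions
   `pᵢ(t) = Σ_{j≤i} e^{rⱼt} / Π_{k≤i,k≠j}(rⱼ − rₖ)`.

The closed-form coefficient of the slowest eigenterm in `O(t)`,
`(n−2)!·α^{n−2}·(δ+rₙ)/Πᵢ<ₙ(rₙ−rᵢ)`, is checked against the
eigendecomposition's coefficient for n = 3…6; its sign is the peak
criterion.

## Numerical choices

- **Zero-mode detection**: `|r| < 1e-10 · max|A|` counts as the zero
  eigenvalue; exactly one is required, else the generator is rejected.
- **Degeneracy**: eigenvalue spacing below `1e-8 ×` the spectral range
  disables every distinct-eigenvalue closed form (Putzer coefficients,
  `t_p`, `ψ`, the slowest pre-exponential factor) in favour of numeric
  routes. A numerically defective eigenbasis (condition number above
  `1e12`) is likewise refused; trajectory evaluation then falls back to
  `scipy.linalg.expm`. Imaginary eigenvalue parts below `1e-10 ×` the
  spectral range are truncated with a logged warning; anything larger is
  treated as a bug signal, since a valid tridiagonal generator cannot have
  them.
- **Stationary distribution** by least squares on the augmented system
  `[A; 1ᵀ]x = [0; 1]`, which stays well conditioned when eigenvalues
  nearly collide, cross-validated against the closed form
  `O_ss = α^m δ / (δ(α+β)^m + γα^m)`.
- **Existence boundary**: `α = δ` (spectrally, `δ + r_slow = 0`) is
  classified as *no peak*, with tolerance `ε = 1e-9 · max(rates)`; at the
  boundary the slowest eigenterm's coefficient vanishes and the waveform
  is asymptotically flat.
- **Numeric peak detector** (`peak_numeric`): the interior maximum is
  located from the **sign change of O′(t)**, not from the amplitude.
  The derivative kills the constant steady-state term, so peaks of any
  relative height remain resolvable — amplitude-based argmax saturates at
  the √eps wall once `ψ` drops below ~1e-12, while genuinely peaked random
  rate sets can have `ψ` as small as 1e-24 with peak times far beyond
  30/|r_slow|. The detector scans a 600-point log grid from
  `1e-3/|r_fast|`, extends the horizon adaptively while the waveform is
  still rising, requires the sign flip to clear a per-point noise floor of
  `1e-12 ×` the summed eigenterm-slope magnitudes (pure round-off in a
  monotone waveform would otherwise masquerade as a peak), and refines the
  bracketed root of `O′` to near machine precision. This replaces a plain
  amplitude-threshold definition, which cannot agree with the analytic
  criterion across the full parameter range.
- **Four-state criterion**: the printed closed form is implemented as
  `α > δ(3 + b + √(1 + 6b + b²))/4` with `b = β/α`, algebraically the
  smaller root of the boundary condition `δ² − (3α+β)δ + 2α² = 0`; it is
  verified against the spectral criterion (and the numeric detector) on
  random draws, as is the three-state rule `α > δ`.

## Limits of the relative peak height

The tabulated extremes of `ψ` are exposed by `psi_limit`: `γ/δ` (α→∞), 0
(α→0, β→∞, γ→0, δ→∞), `α/δ − 1` (γ→∞), divergence (δ→0). Two caveats:

- the **β→0** limit has no clean closed form here; since `ψ` is continuous
  in β through the eigenvalues, the function returns the closed-form value
  evaluated at β = 0 (0 when no peak exists there) rather than guessing a
  symbolic expression;
- the **α→0** and **δ→∞** limits cross the existence boundary: beyond it
  the closed-form expression acquires a negative base under a non-integer
  power (because `δ + r₂ < 0 < δ + r₃`) and is no longer real, and its
  principal-branch modulus does *not* tend to 0. The value 0 is the limit
  of the *waveform* quantity — once the peak is gone, the open probability
  never exceeds its steady state and `ψ = 0` identically — and that is how
  the tests verify those two entries.

## Voltage maps

Gating rates follow Eyring–Polanyi theory, `α = k·e^{(V−V_half)/s}`,
`β = k·e^{−(V−V_half)/s}` (so `αβ = k²` identically). Defaults `k = 1 ms⁻¹`,
`V_half = 0 mV`, `s = 10 mV` are conventional for Kv-channel gating
steepness; the blocker is pinned at its K_d concentration (`γ = δ`), under
which the blocked steady state tends to ½ at strong depolarisation.

Classification of the δ–V plane is deterministic: a grid of points is
labelled A1 (no peak), A2 or A3 by the sign of a central finite difference
(default stencil `dV = 0.5 mV`, well below `s`) of the relative amplitude
`O_p/O_ss^{no-block}`; cells whose stencil straddles the existence border
are labelled A1, since "no peak" is the verifiable statement at the
boundary. A deterministic grid plus bisection replaces random sampling of
the plane so that region maps are exactly reproducible; the Monte Carlo
module provides the stochastic cross-check instead. The β–δ plane scan is
computed for several γ values and asserted identical across them — the
criterion's γ-independence is enforced, not assumed. Only the topology of
the maps (three regions, their monotone trends, the one-gate boundary
`δ = α`) is quantitatively anchored; absolute border coordinates depend on
`k`, `V_half`, `s`, for which no canonical experimental values are bundled.

## Stochastic simulation

Exact Gillespie simulation: dwell time in state `j` exponential with rate
`−A[j,j]`, next state proportional to the outgoing rates in column `j`;
absorbing states legally halt a path. Each channel in an ensemble draws
from `numpy.random.default_rng((base_seed, channel_index))`, so ensembles
are reproducible for a given base seed and independent across channels.
Ensemble open-probability estimates carry the binomial standard error
`√(p̂(1−p̂)/N)`. Defaults: `N = 10⁴` channels, 200 log-spaced grid points.

The simulator emulates idealised voltage-clamp ensembles: independent,
identical channels, no gating or shot noise on the recorded variable, no
series-resistance or leak artifacts, and rate constants frozen within a
step. Agreement of the Monte Carlo estimates with the analytic solution
therefore validates the solver and the simulator against each other; it
says nothing about how well the linear open-block scheme describes any
particular real channel/drug pair, which is an experimental question.

Problem sizes used in the validation suite — ensembles of 10⁴–10⁵
channels, hundreds of random rate sets per equivalence property, six-decade
parameter sweeps — were chosen as comfortable desk-scale settings that
leave the statistical bands far wider than the observed deviations.

## Known limitations

- Closed forms for `t_p` and `ψ` exist only for `m = 1`; for more gates
  the package reports the numeric peak (the existence criterion, however,
  is exact for every `m`).
- The `ψ` closed form near the existence boundary suffers cancellation in
  `δ + r₃`; within ~1e-9 of the boundary the package already reports "no
  peak" by design, so the ill-conditioned strip is excluded.
- Rate sets whose spectrum is numerically degenerate take the slower
  `expm`-based path and report `preexp = NaN` (a defective spectrum has no
  single-eigenterm coefficient).
- The Gillespie loop is pure Python; ensembles of 10⁵ channels take a few
  seconds for millisecond-scale rates. Larger studies would want a
  compiled kernel, which is deliberately out of scope.
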