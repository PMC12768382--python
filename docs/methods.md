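# Methods

## Models

**Discrete two-choice learning equation.** The state `x ∈ [0, 1]` is the
probability of the reinforced response. One trial applies `g₁` with
probability `x` and `g₂` with probability `1 − x`. With the classical
boundary conditions `g₁(1) = 1` and `g₂(0) = 0` the endpoints are absorbing,
and first-step analysis gives the fixation-probability equation
`f(x) = x f(g₁(x)) + (1−x) f(g₂(x))` with `f(0) = 0`, `f(1) = 1`. The
boundary values are carried by the model type itself: the equation is
homogeneous, so without pinning them the only fixed point in general is the
zero function. The predator/prey choice family uses
`g₁(x) = (1−a₁)x + a₁`, `g₂(x) = (1−a₂)x` with `0 < a₁ ≤ a₂ < 1`. When
`a₁ = a₂` the post-trial expectation of the state equals the state
(`x·g₁(x) + (1−x)·g₂(x) = x`), so the process is a bounded martingale and
the optional-stopping closed form is `f(x) = x` — the package's primary
calibration identity.

**Integral (Volterra) form.** The generalized probability-evolution
equation is `Γ(x) = ∫₀ˣ Σᵢ wᵢ(x,t) Γ(ℰᵢ(t)) dt` with non-negative
continuous weights summing to one on `0 ≤ t ≤ x ≤ 1` and continuous
operators `ℰᵢ : [0,1] → [0,1]`. `Γ(0) = 0` holds automatically; no
conditions on the values `ℰᵢ(0)` are needed. Choosing weights `x`, `1 − x`
and evaluating the integrand at `t = x` recovers the discrete equation
(`reduce_to_discrete`). The two-choice case with weights `t`, `1 − t` and
the four-outcome case with weights `pt, (1−p)t, p(1−t), (1−p)(1−t)` are
built-in presets. For the four-outcome presets the weights sum to one
identically in `p`, so the Picard iterates are independent of `p`; the
package verifies this by instantiating models at several rational `p`
values and comparing exact iterates, rather than by carrying `p` as a
symbolic coefficient — the check is equally conclusive and keeps the
polynomial layer univariate in each of `x` and `t`.

**Convergence certificate.** When each `ℰᵢ` is a contraction with
coefficient `κᵢ` and the aggregate `k = Σκᵢ` is strictly below one, the
Picard sequence converges in sup norm to the unique solution in the space
of continuous functions vanishing at 0; the comparison function is the
linear map `φ(t) = k·t`. Two caveats the package deliberately respects:

- The per-step contraction of the *discretized* operator is not asserted to
  equal `k`. Empirically the first-difference ratio for the two-choice
  preset is ≈ 0.463, slightly above `k = 0.45`; the Volterra structure
  (shrinking integration range) is what drives the decay. Solvers therefore
  stop on the *observed* sup-norm successive difference, and the
  `ContractionReport` separates the certificate (`Σκᵢ < 1`, exact) from
  empirical delta ratios.
- The homogeneous integral equation is solved by the zero function, and the
  exact iterates of the built-in presets shrink accordingly
  (`‖Γ₃‖∞ < ‖Γ₂‖∞ < ‖Γ₁‖∞`). The package reports this decay as the
  convergence diagnostic and makes no claim of a nontrivial limit for the
  integral form; the nontrivial solutions live in the discrete form, where
  the boundary pins `f(0) = 0`, `f(1) = 1` select the fixation probability.

## Exact engine

Polynomial weights plus affine operators keep every Picard iterate
polynomial, so the iteration is carried out exactly over `fractions.Fraction`:
composition with `ℰ(t) = st + c` by binomial expansion, multiplication by
the bivariate weight, and term-wise integration
(`∫₀ˣ x^i t^j dt = x^(i+j+1)/(j+1)`). Coefficients are normalized to lowest
terms by the Fraction type after every operation. Degree grows by
`1 + deg_t(w)` per step (by 2 for the built-in presets starting from
`Γ₀(x) = x`), and coefficient bit-length grows quickly, so iteration depth
is capped at 25 by default (`exact.MAX_ITERATIONS`, a config knob).
`Γ₀` defaults to the identity polynomial, matching the worked examples.
One quirk of the four-outcome worked example is documented in the tests:
the displayed final line of its second iterate carries a misprinted
quadratic coefficient, and the engine outputs the exactly-integrated value
`3x²/125` (the cubic and linear terms agree with the display).

Sup norms and deltas of exact traces are evaluated *numerically* on a
10001-point uniform grid. They are diagnostics, not results; the
grid-resolution error is far below the quantities' scale, and exact
maximization of degree-7+ polynomials would buy nothing.

## Numeric engine

- **Quadrature:** composite trapezoid with cumulative prefix sums over the
  variable upper limit; when a weight depends on `x` the engine falls back
  to one trapezoid rule per node (O(n²) per sweep). Simpson refinement was
  rejected: O(h²) is already dominated by interpolation error and keeps
  cumulative evaluation O(n).
- **Interpolation:** `f(ℰᵢ(t))` by piecewise-linear interpolation, which
  preserves `[0, 1]` containment and non-expansiveness; cubic interpolation
  can overshoot and was rejected.
- **Grid:** uniform on `[0, 1]`, endpoints included, `h = 1/(n−1)`;
  node 0 of every integral-form iterate is exactly 0.
- **Stopping:** sup-norm successive difference ≤ `tol` (default 1e−10),
  `max_iter` default 1000. Non-convergence is reported
  (`converged=False`), never raised.
- **Discrete solver:** full (undamped) fixed-point updates with nodes 0 and
  1 pinned to the boundary values. Non-classical boundary operators
  (`g₁(1) ≠ 1` or `g₂(0) ≠ 0`) produce a warning flag, not an error; a
  delta ratio above 0.999 for 50 consecutive sweeps flags the model
  "slow/non-contractive" and returns the current iterate.

Verified behavior: the grid step error against the exact engine shrinks
4.00× per grid doubling on the two-choice preset (501→1001→2001 nodes),
and the discrete solution for `a₁ = 0.3, a₂ = 0.6` moves by less than
2e−4 in sup norm between 501 and 2001 nodes.

## Simulator

The two-choice simulator draws one uniform variate per trial: apply `g₁`
if `u < x`, else `g₂`. The model itself defines no stopping rule for the
"final" probability, so fixation is operationalized by bands
`[0, eps]` and `[1−eps, 1]` with `eps = 1e−6` and a horizon of 10⁵ trials;
censored paths are counted separately and excluded from the fixation-rate
denominator, never assigned to either class. Replicate generators derive
from `SeedSequence((master_seed, replicate_index))`, so runs are
bit-for-bit reproducible and replicates independent. The four-outcome
simulator draws one of four outcomes with probabilities
`p·x, (1−p)·x, p·(1−x), (1−p)·(1−x)` *at the current state x* (the
experiment's outcome table convention, which is what a trial-level process
needs), even though the integral equation writes its weights in the
integration variable `t`; the two conventions are not reconciled in the
model family itself, and the simulator asserts no absorbing structure for
four-outcome models — it reports trajectories and censoring as observed.

What the simulator emulates is the idealized trial-level Markov process —
i.i.d. conditionally on the state, stationary operators, no drift in the
learning rates. Passing calibration therefore shows the solvers and the
process definition are mutually consistent; it says nothing about fit to
real behavioral data (fitting is out of scope).

Default problem sizes (10⁴ replicates for calibration runs, 1001-node
grids, iterate depth 3) were chosen to make the Monte-Carlo standard error
(≈ 0.005) small against the closed-form targets while keeping any single
check in the seconds range.

## Known limitations

- The exact engine requires polynomial weights and affine operators;
  generic continuous weights/operators are numeric-engine only, and their
  Lipschitz constants are grid estimates that never yield a `certified`
  report.
- Only the linear comparison function `φ(t) = k·t` is implemented; the
  a-priori iteration bound assumes it.
- No closed-form limiting solutions, power-series solution ansatz, or
  fitting of operators to empirical data.
- The CSV export targets 12 significant digits; exact coefficients are
  available through the JSON listing or `--exact`.
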