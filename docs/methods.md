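# Methods

## Model

`gaitstab` implements a one-dimensional model of walking balance: a
linearized single-link inverted pendulum under proportional-derivative
foot-placement control.  The body is a point mass at position `x` with
velocity `v`, connected by a rigid massless leg to a ground contact point
`p`.  Linearizing about the upright configuration gives

    dx/dt = v,        dv/dt = omega^2 (x - p),

with eigenfrequency `omega = sqrt(g / l)` (`g` = 9.81 m s^-2, `l` the
effective leg length).  Between steps `p` is constant and the solution is
the hyperbolic flow

    x(t) = p + (x0 - p) cosh(omega t) + (v0 / omega) sinh(omega t)
    v(t) = (x0 - p) omega sinh(omega t) + v0 cosh(omega t).

The velocity line is the exact time derivative of the position line; we
verified it against a high-accuracy Runge-Kutta integration of the ODE
(test oracle only — the library itself never integrates numerically, so
simulated states carry no discretization error at any sampling interval).

Steps are instantaneous shifts of `p`, taken every `t_step` seconds, with
no collision or energy loss.  The new placement is a PD law on the CoM
state relative to the contact point at *midstance*, defined in the model
as the temporal midpoint between steps:

    progressive:  p[n+1] = p[n] + b_o        + b_p q[n] + b_d v[n]
    alternating:  p[n+1] = p[n] + (-1)^n b_o + b_p q[n] + b_d v[n]

with `q = x - p`.  Progressive stepping models anterior-posterior
walking (the CoM passes over each new contact), alternating stepping
models medial-lateral sway (the offset direction flips each step).  The
parity convention starts at `(+1)` for step 0; which physical side that
is, is a labelling choice.

Time convention: `t = 0` is a midstance; steps occur at
`t = (n + 1/2) t_step` and midstances at `t = n t_step`.  A perturbation
scheduled exactly at a midstance or step event is applied *before* that
event, so the controller senses the perturbed state (this is what makes
a perturbation at a midstance propagate through the transition matrix
from that very step).

## Parameters

| parameter | meaning | units | default / example |
|---|---|---|---|
| `omega` | pendulum eigenfrequency `sqrt(g/l)` | s^-1 | 3.13 (leg ~1 m) |
| `b_o` | constant placement offset (step length/width) | m | -0.05 ap / 0.02 ml |
| `b_p` | proportional gain on midstance `q` | – | 2.5 |
| `b_d` | derivative gain on midstance `v` | s | 0.6 |
| `t_step` | step duration (`= 60 / cadence`) | s | 0.5 (120 steps/min) |

The worked example throughout the package and its tests uses these
values; they produce a stable walker in both stepping modes.

## Periodic orbits

With `c = cosh(omega t_step / 2)`, `s = sinh(omega t_step / 2)`, the
relative state has a closed-form periodic orbit whose midstance reference
is

    progressive:  q_ref = 0,                     v_ref = b_o / (2s/omega - b_d)   (period t_step)
    alternating:  q_ref[n] = (-1)^n b_o / (2c - b_p),  v_ref = 0                  (period 2 t_step)

On the measure-zero lines `b_d = 2s/omega` (progressive) and `b_p = 2c`
(alternating) the denominators vanish and no such orbit exists;
`periodic_orbit` raises `SingularOrbitError` there (tolerance 1e-12 on
the denominator) rather than returning infinities.

## Step-to-step stability

Midstance deviations from the orbit propagate linearly,
`delta[n+1] = A delta[n]`, with the constant transition matrix

    A = [[c^2 + s^2 - c b_p,   (2s/omega - b_d) c],
         [(2c - b_p) s omega,  c^2 + s^2 - s omega b_d]].

`A` is the Jacobian of the exact (affine) midstance-to-midstance map; the
tests confirm this by central finite differences over randomized
parameters.  `b_o` does not appear, so the offset never affects
stability, and both stepping modes share the same `A`.

Eigenvalues are computed in closed form from trace and determinant
(quadratic formula; for a complex pair the modulus is `sqrt(det)`).  This
keeps boundary cases exact — an iterative eigensolver would blur the
eigenvalues of exactly ±1 on the region edges.  The orbit is called
asymptotically stable when the spectral radius satisfies
`rho(A) < 1 - 1e-12`; points with `|rho - 1| <= 1e-12` are reported as
marginal and not stable.

Stability is equivalent to three closed-form inequalities,

    b_p < 2c,    b_d > 2s/omega,    b_d < b_p c / (omega s),

an open triangle in the gain plane with vertices `(2s^2/c, 2s/omega)`,
`(2c, 2s/omega)`, `(2c, 2c^2/(omega s))`.  On the edge *segments* of the
triangle `rho = 1` exactly (eigenvalue -1 on `b_p = 2c`, +1 on
`b_d = 2s/omega`, a complex unit-modulus pair on the third edge); note
that on the full lines beyond the vertices the second eigenvalue exceeds
1 in modulus, so the unit-spectral-radius property belongs to the
segments, not the lines.  The inequality and eigenvalue criteria are
checked against each other on randomized grids in the tests.

The constant-offset-from-XCoM placement rule (extrapolated center of
mass `q + v/omega`) corresponds to gains `b_p = c + s`,
`b_d = (c + s)/omega`; for the example system this gives `rho = 0.21`
with `det(A) = 0` to machine precision — a near-deadbeat controller.

## Cadence dependence

With `t_step = 60 / cadence`, the triangle's projections onto the gain
axes are `b_p in [2s^2/c, 2c]` and `b_d in [2s/omega, 2c^2/(omega s)]`.
Three of the four endpoints are strictly decreasing in cadence — slower
walking requires higher gains, the model's central behavioural
prediction.  The upper derivative-gain endpoint `2c^2/(omega s)` is an
exception: `d/da [cosh^2(a)/sinh(a)]` changes sign at `a = asinh(1)`, so
it has a minimum at cadence `30 omega / asinh(1)` (≈ 106.5 steps/min for
`omega = 3.13 s^-1`) and rises again at faster cadences.  The overall
upward shift of the region for slower walking is unaffected; the
non-monotonicity of this single endpoint is asserted explicitly in the
tests (`TestCadenceSweep`), verified independently against a dense
spectral-radius grid.

## Gain estimation

Because the placement law is linear in the midstance state, the
step-to-step placement shift `delta_p[n] = p[n+1] - p[n]` regressed on
`(q[n], v[n])` identifies `b_p` and `b_d` as OLS slopes.  The regression
target is the placement *shift* (not the absolute placement), which makes
the identification exact by construction; it is validated by parameter
recovery on synthetic walkers rather than by a symbolic mapping.
Progressive data use a plain intercept (estimating `b_o`); alternating
data include an explicit parity regressor `(-1)^n` whose coefficient
estimates `b_o` — equivalent to sign-folding odd steps but with simpler
diagnostics.  Fits go through statsmodels OLS; the headline diagnostic is
adjusted R², plus adjusted R² of the two single-predictor refits and
per-slope standard errors.  No p-value gating or multiple-testing
machinery: one model per dataset.

Degenerate designs fail loudly: noise-free on-orbit data have
zero-variance regressors and raise `SingularDesignError` naming the
offending columns (minimum sample sizes: 3 progressive, 4 alternating).

## Synthetic gait

`generate_noisy_walk` starts on the deterministic periodic orbit and adds
Gaussian motor noise `eps ~ N(0, sigma_p^2)` to each realized placement —
the minimal noise structure under which OLS estimation is consistent.
Optional sensory noise corrupts only what the controller senses; the
recorded true states always satisfy the closed-form dynamics exactly.
Each noise channel draws from its own seeded substream
(`SeedSequence.spawn`), so toggling one channel never shifts another's
draws, and every dataset is a pure function of (parameters, noise spec,
seed, n_steps).

Two consequences worth spelling out, both asserted in the tests:

* Controller-side sensory noise does **not** bias the slope estimates.
  It enters the regression as response noise independent of the same-step
  regressors (it only feeds *future* states), so OLS remains consistent —
  it merely inflates the residual variance.
* The classical attenuation-toward-zero appears when the *recorded*
  states are measured with error (errors-in-variables), as with imperfect
  motion capture.  Corrupting the recorded `q, v` columns biases both
  slopes low.

For stable parameters the stationary midstance deviation covariance
solves the discrete Lyapunov equation `Sigma = A Sigma A' + sigma_p^2 g g'`
with noise input `g = (-c, -omega s)'` (a placement error shifts the
post-step relative position by its negative, then flows half a step);
the generator's empirical covariance is checked against
`scipy.linalg.solve_discrete_lyapunov`.

Unstable walkers with noise diverge; the generator aborts with a
`DivergenceError` (reporting the step reached) when `|q|` exceeds a
configurable bound, default 10 m.

Noise magnitudes are conventions, not measurements: the fixtures use
`sigma_p = 0.01 m`, chosen to produce placement variability of roughly
human scale (~1 cm s.d.).  What the generator emulates is exactly the
statistical structure the estimator assumes — linear placement law plus
i.i.d. placement noise.  Real gait data violate it in known ways (pelvis
markers approximate the CoM, functional rather than temporal midstance,
ankle-roll and step-timing control, non-stationarity), so passing
recovery tests demonstrate estimator correctness under the model, not
fidelity of the model to human walking.

## Numerical choices

* Closed-form propagation everywhere in the library; RK integration
  exists only as a test oracle.
* Problem sizes in tests: recovery uses 1000-step walks over 20 seeds
  (estimates average within ±0.05 of truth); the Lyapunov check uses a
  single 20 000-step walk; criterion equivalence uses 10^4 randomized
  parameter tuples.  These sizes give sampling error comfortably below
  the asserted tolerances.
* CSV output uses 12 significant digits, dot decimal separator, with
  provenance comment headers; round-trips are lossless to ~1e-12
  relative.
* Trajectory sampling snaps the grid to divide `t_step` inside the noisy
  generator; the event-driven simulator accepts any `dt` and resolves
  events exactly with a 1e-9-scaled time tolerance for grid/event
  coincidences.
* Seeds: `numpy.random.SeedSequence(seed).spawn(3)` for the three noise
  channels.

## Known limitations

One-dimensional, linearized, collision-free dynamics with constant step
timing and constant leg length; no ankle-roll or step-time feedback; no
swing-leg dynamics.  Stability here is local asymptotic stability of the
periodic orbit — no claim about robustness to large perturbations,
viability, or a graded "degree of stability".  The estimator assumes the
model's temporal midstance and true CoM states; applying it to real
motion capture introduces the errors-in-variables bias documented above.
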