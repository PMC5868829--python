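# Methods

## Model

All modules share one delayed negative-feedback model of Cdk1–cyclin B /
APC/C antagonism. Cyclin B–Cdk1 activity `x` (nM) is produced at a constant
synthesis rate and removed by APC/C-dependent degradation, with the APC/C
responding to Cdk1 activity one delay ago through a Hill function:

```
dx/dt = k_s − b_deg · x · H(x(t − τ)),    H(x) = xᵐ / (Kᵐ + xᵐ).
```

Defaults follow physiological ranges for the early embryonic cycle:
k_s ∈ [1, 1.5] nM/min, b_deg ∈ [0.04, 0.4] min⁻¹, K = 32 nM, m ≥ 15,
τ ∈ roughly [5, 40] min. The dimensionless balance ratio
`c = k_s / (b_deg · K)` controls where the fixed point sits relative to the
activation threshold; oscillations of the sharp-switch limit require
0 < c < 1.

The Hill function is evaluated as `expit(m · ln(x/K))`, which is
algebraically identical to the power form but immune to overflow at large m,
and degrades gracefully to the Heaviside step at m = ∞ (`INFINITE_M`).

### Delay formulations

1. **Discrete.** A single lag τ. The fixed point solves
   `k_s = b_deg · x* · H(x*)` (unique because the right side is strictly
   increasing); linearizing, a perturbation obeys `u' = −A·u − B·u(t−τ)` with
   `A = b_deg·H(x*)`, `B = b_deg·x*·H'(x*)`. A Hopf crossing exists iff
   B > A, at `ω = √(B²−A²)`, `τ_c = arccos(−A/B)/ω`. Both A and B scale with
   b_deg, so `b_deg·τ_c` depends only on (c, m); at m = 15 it is minimized
   near c = 0.5, which is why equal S/M phases also minimize the delay needed
   to oscillate.

2. **Relay (m → ∞).** The loop alternates between pure accumulation
   (`x' = k_s`, APC/C off) and exponential decay toward cK (APC/C on), each
   phase extended by exactly one delay because switches lag the threshold
   crossing. Solving piecewise:

   ```
   degradation time  = τ + (1/b_deg) · ln(1 + (c/(1−c)) · b_deg·τ)
   accumulation time = τ + (1/b_deg) · ((1−c)/c) · (1 − e^(−b_deg·τ))
   x_max = K + k_s·τ,    x_min = K·(c + (1−c)·e^(−b_deg·τ))
   ```

   An independent event-driven solver advances the exact piecewise solution
   between scheduled switches and reproduces the closed form to 1e-8 min on a
   20×20 (c, τ) grid (a frozen test).

3. **Gamma-distributed.** The lagged activity is replaced by an average over
   the past weighted by a Gamma density with integer shape N and rate
   a = N/τ_avg. Via the linear chain trick this is *exactly* an
   (N+1)-dimensional ODE chain; no history integral is ever discretized.
   Stability follows from the chain Jacobian's spectrum: the Hopf boundary in
   τ_avg is located by scanning the largest eigenvalue real part on a
   log-spaced grid and refining each sign change by bisection. N = 1 never
   oscillates in the physiological box; N = 2 destabilizes and then
   re-stabilizes (two crossings); the first crossing decreases monotonically
   toward the discrete τ_c as N grows.

4. **State-dependent.** APC/C becomes an explicit relaxation variable so the
   lag can be read off the current state:

   ```
   dx/dt = k_s − b_deg · x · a
   da/dt = β · (H(x(t − τ(a))) − a)
   τ(a)  = τ1 + (τ2 − τ1) · aᵖ / (0.5ᵖ + aᵖ)
   ```

   The delay switches smoothly from the activation lag τ1 (APC/C low) to the
   inactivation lag τ2 (APC/C high) with steepness p. For τ1 = τ2 and large β
   the discrete model is recovered (verified within 2% on the period at
   β = 50). The lag is evaluated from the *current* APC/C activity — explicit
   state dependence, no implicit equation per step.

## Numerics

- Fixed-step classical RK4 with the method of steps. Past values are stored
  on the uniform grid and read back by cubic Hermite interpolation
  (value + derivative at the bracketing nodes), keeping the overall scheme
  high-order; when the lag is shorter than one step the scheme falls back to
  linear extrapolation within the current step. Kernels are numba-compiled.
- Resolution guards reject steps coarser than τ/20 (discrete), 0.1/a
  (chain) or min(τ1, τ2, 1)/20 (state-dependent); defaults are much finer
  (dt = 0.01–0.02 min). Halving dt changes late-time discrete-model
  trajectories by < 0.1% (tested).
- The relay solver is event-driven and exact: switch times come from logs
  and ratios, not stepping; dense output is sampled from the closed-form
  segments afterward.
- Feature extraction discards the first half of each trajectory (transient),
  finds interior extrema by sign changes of the first difference (plateaus
  carried), refines each by a local parabola, and reports the mean peak
  interval as period. A trajectory counts as oscillating when the
  peak-to-trough amplitude exceeds a floor of 0.032 (10⁻³ of the canonical
  32 nM threshold, i.e. far above integration noise and far below any real
  cycle), at least 3 full cycles are seen, and the cycle-interval coefficient
  of variation is below 5%.

## Cascade step responses and delay fitting

APC/C activation by n sequential Cdk1-catalyzed phosphorylations at rate
k·[Cdk1] per step gives an active-fraction step response equal to the
Erlang/Gamma CDF with shape n — the mechanistic reading of the Gamma delay.
`fit_gamma_delay` fits shape (integer grid 1–30) and mean (bounded continuous
minimization) to a normalized rise-to-plateau curve, profiling the plateau
amplitude analytically at each candidate, so noiseless Gamma-CDF inputs are
recovered exactly. With 5% multiplicative noise the mean delay is recovered
within 10% across 100 seeded replicates (tested).

An optional uniform dephosphorylation back-rate (`k_back`, default 0) gives
the chain a partial steady state at intermediate Cdk1 levels; starting from
such a pre-activated state shortens the measured delay several-fold relative
to starting from rest, which is why step-measured delays need not equal the
effective delay in the oscillating loop.

`generate_synthetic_response` produces seeded synthetic step-response curves
(plateau × Gamma CDF with multiplicative Gaussian noise) standing in for
digitized degradation-rate measurements; its defaults (shape 4, mean 40 min,
241 samples over three means) are the reference experimental conditions and
are used unchanged in the recovery tests.

## Headline-number scans (`scripts/acceptance.py`)

- **t4**: closed-form relay period on b_deg ∈ [0.04, 0.4] (37 points) ×
  τ ∈ [0, 20] min (81 points) at k_s = 1.25, K = 32; reported value is the
  largest τ whose period lies in the realistic 20–30 min band.
- **t5**: state-dependent model at k_s = 1.2, b_deg = 0.125, K = 32, m = 20,
  β = 5, p = 5 on a 15 × 15 (τ1, τ2) grid over [0, 15]²; cells with S/M
  durations equal within 10% of the period and period 25 ± 2 min; value is
  the mean τ1 + τ2 over those cells.
- **t6**: same model with τ1 + τ2 = 15 min fixed, k_s = 1.25, on
  25 b_deg values × 16 τ1 values; cells with near-equal phases and period in
  the realistic 20–30 min band; value is their median b_deg. The 20–30 min
  band (rather than a narrow 25 ± 2 window) defines the "realistic period"
  region; a narrower window would bias the central b_deg upward because the
  equal-phase locus crosses the region near a ~27 min period at low b_deg.

Grid sizes are this package's own choice, sized so each scan completes in
seconds while sampling the axes densely enough that the selected-cell
statistics are stable under refinement. All three targets are deterministic.

## Limitations

- Fixed-step explicit integration: no adaptive error control; accuracy is
  established by convergence tests and exact oracles rather than local error
  estimates.
- The state-dependent solver evaluates the lag explicitly from the current
  APC/C activity; formulations where the lag solves an implicit equation are
  out of scope.
- The cascade's cooperative last step is exposed only as a multiplicative
  rate factor (γ, default neutral); no saturating or allosteric variants.
- Feature extraction assumes roughly periodic signals after the transient;
  strongly modulated or chaotic regimes are classified "not oscillating"
  by the interval-CV criterion rather than analyzed further.
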