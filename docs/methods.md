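# Methods

## The model

A hoverfly released in free fall must start flapping and re-orient its
thrust within a fraction of a second to avoid the floor.  `hoverfall`
implements a planar (corridor-axis x, height z) closed-loop model of that
recovery in which the only sensory inputs are translational optic flow and
halteres pitch-rate feedback — no graviception, and in the basic variant no
absolute attitude reference at all.

State and conventions: z up, floor at z = 0, release at z = 0.40 m; pitch
θp = 0 horizontal, negative head-down, physiological range [−π/2, π/2].
Forces are mass-normalised (m/s²).  The wing force is orthogonal to the body
axis (helicopter analogy), so

    L = cos(θp)·|F|      (vertical lift)
    T = −sin(θp)·|F|     (horizontal thrust)

and the kinematics integrate v̇z = −g + L, v̇x = T at the camera sample
period Ts = 1/1600 s (forward Euler on velocity, trapezoid on position, so
an unforced fall reproduces the ballistic closed form exactly).

The translational optic flow seen at distance d_wall = 0.20 m from the wall
has magnitude |ω| = |V|/d_wall and points opposite to the velocity; its
fly-frame components subtract the body pitch:

    θ_flow = atan2(vz, vx) + π − θp
    ωx = |ω| cos(θ_flow),   ωz = |ω| sin(θ_flow)

With this sign convention ωz > 0 while falling and the forward component ωx
goes negative as the body pitches down — the controller regulates ωx toward
a setpoint of 0.04 (a dimensionless constant on the internal |V|/d scale;
the source material prints it with inconsistent units, so it is treated as a
model unit and exposed in the configuration).

### Dynamic blocks

All blocks are continuous-time rational transfer functions discretized once
with the bilinear (Tustin) transform at Ts and stepped inside the loop
(direct form II transposed).  Tustin preserves DC gain and stability at any
sample period; sample k of a step response corresponds to the continuous
midpoint (k+½)Ts, which the tests account for when comparing against
partial-fraction and `scipy.signal.lsim` oracles.

* **Wing force** C_WB(s) = (0.24 s + 1.8955)/(0.01 s² + 0.1 s + 1), driven
  by a step of amplitude g = 9.81 from wingbeat onset.  Coefficients are in
  seconds (the prose time constants "0.01 ms / 0.1 ms" cannot reproduce the
  second-scale transient; taken at face value in s).  The response peaks at
  25.8 m/s² (≈2.6 g) near 0.22 s, reads 20.3 m/s² at 0.4 s and settles at
  1.8955·g ≈ 18.6 m/s².
* **Passive pitch** T_passive(s) = (0.001 s² + 30 s)/(s²(0.0011 s³ +
  0.0005 s² + 0.01 s + 1)), driven by a −π/2 step from release: the
  nose-down tumble imposed by the glued pin before the wings engage.  This
  fitted transfer function has a pair of unstable complex poles
  (4.53 ± 8.65j rad/s): it is valid only over the ≤150 ms fall window it was
  fitted on, and is used for nothing else.  At the latest onsets it hands
  the controllers θp ≈ −0.87 rad and θ̇p ≈ −23 rad/s.
* **Halteres pitch-rate loop**: PI controller (Kp = 7, Ki = 0.3, measured
  values for the reflex) acting through a first-order wing-pitch actuator
  lag (2 ms, one wing-stroke correction time) under unity feedback.  The
  loop is implemented as the algebraically reduced closed-loop transfer
  function (Kp s + Ki)/(τ s² + (1+Kp) s + Ki) rather than a per-sample loop,
  avoiding an artificial one-sample delay; at onset its state is initialised
  so the output continues the passive pitch rate.  Note the loop's
  proportional action brings tracking to Kp/(1+Kp) = 0.875 within
  milliseconds, but the integral time constant is (1+Kp)/Ki ≈ 27 s — "zero
  steady-state error" is asymptotic, not something visible on the 3 s
  simulation horizon.
* **Visual PD** on the forward-flow error: Kp + Kd·s/(τ_d s + 1).  The
  derivative filter constant is unspecified in the source; τ_d = 0.01 s is
  used (tames 1600 Hz noise, fast relative to the loop), applied to the
  error, and exposed in the configuration.

The optic-flow measurement is fed back with a one-sample (0.625 ms) sensor
delay, far below any loop time constant.

### Variants

**Basic**: θ̇p* = PD_V(ωx* − ωx), tracked by the halteres loop; |F| follows
the open-loop C_WB step.  **Improved** adds, in parallel (the junction
algebra is a design choice; the source shows parallel summation without
formulas): a PI force loop |F| += Kp_wz·ωz + Ki_wz·∫ωz (the integrator nulls
the vertical flow while retaining the steady lift needed to hover; the total
force is clamped ≥ 0 because flapping cannot pull along the negative body
axis), and an absolute-pitch PD θ̇p* += −Kp_θ·θp − Kd_θ·θ̇p.

A divergence guard halts a run when |θp| > π or |v| > 50 m/s, flagging it
`diverged`, so unstable ensembles stay finite.

## Parameters

| parameter | default | units | origin |
|---|---|---|---|
| d_wall | 0.20 | m | corridor half-width |
| g | 9.81 | m/s² | gravity |
| Ts | 1/1600 | s | camera frame period |
| Kp_H, Ki_H | 7, 0.3 | – | halteres PI, prior measurements |
| actuator lag | 0.002 | s | one wing-stroke correction time |
| ωx* | 0.04 | model OF units | forward-flow setpoint |
| Kp_V, Kd_V | 5.0, 0.3 | – | identified (see below) |
| τ_d | 0.01 | s | derivative filter (design choice) |
| Kp_θ, Kd_θ | 100, 2 | 1/s, – | improved model, tuned (see below) |
| Kp_wz, Ki_wz | 6, 80 | – | improved model, tuned (see below) |
| onset window | [0.075, 0.150] | s | wingbeat-initiation range |

**Visual gains.**  The study identified (Kp_V, Kd_V) from recordings that
are not deposited; the original estimates are likewise not in the available
text.  The package defaults (5.0, 0.3) were chosen so the basic model
reproduces the reported phenomenology: a clean recovery over the first
~200 ms after onset (positive climb before the 300 ms window closes) and a
detectable instability with ensemble median ≈ 0.4 s from the start of the
fall.  The instability timing is insensitive to this choice — across
Kp_V ∈ [3, 10], Kd_V ∈ [0.1, 1] the median stays within 0.33–0.49 s —
because the divergence is structural (three integrators between the
measured flow and the commanded pitch), not a gain artefact.

**Improved-model gains.**  The source sets these manually in a figure and
table that are not in the available text.  The defaults were tuned, once,
against the two behaviours the study reports for this variant: onset-aligned
mean pitch back within ±0.1 rad of its final value in under 150 ms for all
three onset groups, and zero crashes over 150 three-second falls.  With
Kp_θ = 100, Kd_θ = 2 the inner pitch loop has an effective time constant
(1+Kd_θ)/Kp_θ = 30 ms; Kp_wz = 6, Ki_wz = 80 give the heave loop
ω_n = √(Ki_wz/d_wall) ≈ 20 rad/s at near-critical damping.  Stronger pitch
gains (Kp_θ ≳ 150) destabilise the cascade against the 2 ms actuator lag.

## Gain identification

The likelihood objective is not specified in the source; Gaussian iid
residuals on the pitch time series over a 200 ms post-onset window are used,
with residual scale σ = 0.08 rad — the pitch measurement error of the
stereo reconstruction (≈ ±5°).  Pitch is the natural matched signal (it is
the controlled state and the best-measured one); position-based objectives
are a configurable alternative left unexplored.  For each candidate
(Kp_V, Kd_V) on a grid over [0, 20] × [0, 2] the model is simulated with the
trial's observed onset; a simulation that diverges inside the window scores
−∞.  Per-trial maps are averaged element-wise and the optimum read off the
averaged map, ties broken toward smaller Kd_V then smaller Kp_V (lowest
complexity).  Default grid 41×41; the analysis scripts use 21×21
(steps 1.0 and 0.1), which bounds the recovery statement "within one grid
cell" at ±1.0 / ±0.1 and keeps the 44-trial averaging under half a minute on
one CPU.

Recovery at the study's conditions (44 selected trials, 0.08 rad noise) is
exact on the grid; a noiseless self-generated trajectory peaks exactly at
its generating point.

## Synthetic cohorts

The generator emulates the recordings the analysis chain was built for: 57
trials; onset times from a lognormal calibrated so the mean after truncation
to [75, 150] ms is the measured 103 ms (shape 0.28, ~95% of the open-form
mass in [60, 180] ms); 13/57 trials non-recovering, alternating between a
delayed onset (> 150 ms) and a never-engaging force loop, so both clauses of
the selection filter are exercised; body length uniform in 10–15 mm; head
and tail landmarks at ± half the body length along the axis, perturbed by
0.08 rad per-frame pitch noise and 0.5 mm per-landmark position noise
(the stereo quantization scale).  Pitch is then *measured back* from the
landmarks by the same two-regression procedure used on real frames (yaw in
XY, counter-rotate, pitch in ZX).

What the cohort does **not** emulate: real wing aerodynamics and body drag,
yaw/roll motion and curved corridor paths, tracking dropouts when the fly
faces the camera, non-Gaussian tracking outliers, and any mismatch between
the true fly controller and the model family being fitted.  Passing the
round-trip tests therefore shows the pipeline is correct and well-posed at
the stated noise — not that the model family is the right description of
real flies.

## Numerical choices and degenerate inputs

* Trial selection truncates each kept trajectory at its first positive-vz
  sample or 300 ms after onset, whichever is first; likelihoods then use
  whatever window remains (at least 100 ms is required).
* Settling time requires the trailing in-band stretch to last ≥ 50 ms —
  the final sample is trivially within any band of itself.
* Instability onset: first sample with |θp| > π/2 or forward-flow error
  exceeding 10× its value at onset (both thresholds configurable; the
  "highly unstable" of the source is visual, this is its operationalisation).
  A run halted by the divergence guard before either trigger reports the
  guard time.
* Group means are onset-aligned and truncated at the shortest group member.
* `accel_from_positions` double-differentiates by central differences, then
  smooths (Savitzky–Golay, order 1, window 11; filter-after-differentiation);
  the outermost samples are edge-padded and the first/last 6 samples carry
  filter edge effects.
* Degenerate landmark clouds (vertical in XY) fall back to the principal
  component axis and are flagged; a flat passive-pitch series makes the
  transfer-function re-fit report `degenerate` instead of coefficients.
* The quantization uncertainty Δd/√12 evaluates to 0.74–1.35 mm over the
  rig's Δd range; the source prints [0.46; 0.62] mm for the same formula.
  The formula is implemented as printed and the discrepancy left visible.

## Problem sizes

The analysis drivers and the acceptance script use 45-fall ensembles
(150 for the improved-model driver), 57-trial cohorts with 44 selected, and
21×21 grids; these sizes give group occupancies and map averages comparable
to the study's (150 simulations, 44 maps) while each script completes in
well under a minute.

## Known limitations

Planar dynamics only; no body drag or aerodynamic damping, so the basic
model's divergence rate may be faster than a real fly's; the improved-model
gains are this package's calibration, not measured values; the passive
pitch transfer function must never be evaluated beyond ~0.2 s (unstable
poles); the optic-flow scale is internally consistent but not anchored to
rad/s of a real eye because of the unit ambiguity in the source setpoint.
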