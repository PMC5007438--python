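# Methods

This note records the models, parameter choices and numerical conventions
behind `optoloop`, and what the simulated experiments do and do not show
about wet-lab behaviour.

## Expression plant

The raw model is a linear chain: mRNA produced at `b_r0 + b_r_gain·u` and
degraded at `d_r`; immature protein produced at `b_p·r`, diluted at `d_p`
and maturing at `k_m`; fluorescent protein produced at `k_m·p` and diluted
at `d_p`. Dividing each species by its un-induced steady state gives the
fold-change coordinates used everywhere else:

    dR/dt = d_r (1 − R) + b_r u,   dP/dt = (d_p + k_m)(R − P),
    dG/dt = d_p (P − G),           b_r ≡ b_r_gain · d_r / b_r0.

This recoordinatization makes the rest state exactly (1, 1, 1), makes
deviations from rest exactly linear (superposition holds to solver
tolerance), and gives the steady-state law `G_ss = 1 + (b_r/d_r) u`; with
the nominal fitted rates `b_r/d_r = 1.0094`, so `u = 1` yields
`G_ss = 2.0094`. Note that a variant sometimes written as
`dR/dt = b_r(1+u) − d_r R` was rejected: it breaks the exact (1,1,1) rest
state whenever `b_r ≠ d_r` and with it the fold-change interpretation of the
measurement pipeline.

Integration is adaptive LSODA at `rtol 1e-8 / atol 1e-10` (tightened in
oracle tests), restarted at every input breakpoint so zero-order-held
inputs are exact. Trajectories are clipped at zero only as a guard; the
dynamics never cross zero for admissible inputs.

## Dose-response map and the scale of the PI gains

The dose-response `u = f(U)` is a Hill curve with zero basal offset,
`f(U) = u_max U/(K + U)` with defaults `u_max = 1.2`, `K = 3` (% green).
Only its qualitative features are published — `f(0) = 0`, monotone,
nearly flat above 60% intensity — so the two constants are package choices,
fixed by a discrete-loop stability analysis *before* any end-to-end scoring:
the published PI gains (80, 8) and (160, 20) act on errors in fold-change
units and command intensities in percent, so the loop gain is
`K_P · f′(U*) · |H|` at the operating intensity `U*`. With the defaults,
`f′ ≈ 0.011 per %` around the `G = 2` operating point, which puts (80, 8) at
a ~55° phase margin and (160, 20) at a comfortable margin as well, while
`f(100) − f(60) ≈ 1.9% of f(100)` preserves the near-flat saturation. A
half-saturation of a few percent of maximal LED power reflects a highly
light-sensitive induction system. Gain magnitudes are inherently
scale-dependent; had the loop been formulated in raw fluorescence units the
same gains would correspond to a different dose-response normalization.

The PI integral term is clamped to [0, 30] % for the expression loop: the
dose-response is nearly flat above ~30% intensity, so any larger integral
state encodes saturation time (windup) rather than useful actuation, and
the clamp is what limits overshoot after the start-up transient. The growth
loop keeps the published [0, 60] clamp it was tuned with. No anti-windup
beyond clamping is implemented.

## Discretization, delay, disturbance channel

`discretize` computes the exact ZOH transition pair `(Ad, Bd)` from the
augmented matrix exponential at `T_s = 10` min. The commanded input reaches
the plant one sampling period late (actuation/biology lag), implemented as
a one-slot command buffer in the scenario runner and as a pending-input
term in the MPC prediction. The additive disturbance `d` enters through the
same input column: it is zero in the nominal system and is estimated at
every measurement to flag perturbations.

## Adaptive model for estimation

The particle-filter/MPC model class is a *baseline-frozen* variant of the
fold-change model: production coefficients stay at the calibration-day
rates while degradation/dilution use the current estimates,

    dR/dt = d_r0 + b_r u − d_r R,
    dP/dt = (d_p0 + k_m0) R − (d_p + k_m) P,
    dG/dt = d_p0 P − d_p G.

Rationale: the measured output remains normalized to the pre-perturbation
baseline for the whole experiment, so a dilution-rate increase (e.g. an
M9→LB medium shift) *lowers the measured level* — in a pure fold-change
parameterization `d_p` cannot affect the steady level at all, and the
filter would be structurally unable to attribute such a shift to `d_p`.
The baseline-frozen form reduces exactly to the nominal model when the
estimates equal the calibration values (its affine drift `fd` vanishes), so
`discretize` keeps its fixed-rest-state contract and the adaptive variant
is a separate constructor (`discretize_adaptive`).

## Particle filter

Bootstrap filter with N = 2000 particles over (state deviation, log-rates,
d). Measurement likelihood is Gaussian with sd = 3% of the signal (floor
0.01); systematic resampling fires when the effective sample size drops
below N/2; parameters evolve through a Liu-West shrinkage kernel
(a = 0.98) on log-rates with a jitter floor of 0.02 added to the kernel
covariance — without the floor the parameter cloud collapses once converged
and can never track a mid-run change. The disturbance follows a bounded
random walk (sd 0.01 per step, bounds ±2); keeping it slow is deliberate,
so that sustained model mismatch is shared with the parameters rather than
absorbed instantly by `d`. Missing measurements propagate the ensemble
without reweighting. All randomness flows from one generator, so a fixed
seed reproduces runs bit-for-bit.

## MPC

Horizon N = 6 (1 h), decision variables are the next N fold-change inputs
bounded to [0, f(60)] — the 60% intensity cap reflects the flat
dose-response above that level. The cost is the squared output-tracking
error over the horizon plus a small input-increment penalty (weight 1e-3);
because the model is linear this is a box-constrained linear least-squares
problem solved exactly (BVLS), making every solve deterministic. The first
input is mapped to an intensity through the inverse dose-response. The
optimal cost is monotonically non-decreasing in the horizon length: a
longer horizon includes every stage of the shorter one plus nonnegative
extra stages (the test suite asserts this direction).

## ML calibration and identifiability

`fit_model_ml` maximizes the Gaussian likelihood (equivalently nonlinear
least squares over log-rates, trust-region-reflective with bounds,
multistart around the nominal values). Noise-free characterization data
returns the generating rates to machine precision. Two structural caveats,
both visible in the tests: (i) the u→G transfer function has no zeros, so
the pole set {d_r, d_p+k_m, d_p} is identified only as an unordered set —
initializing near the nominal values selects the physical labeling (mRNA
turnover fastest); (ii) at realistic noise the fast mRNA pole (62% decayed
within one 10-min sample) and the small difference between the two slow
poles make `d_r` and `k_m` individually ill-determined, while `d_p` and
especially the control-relevant gain ratio `b_r/d_r` (≈1% error at 5%
noise) are sharply identified. The package reports per-fit RMSE and a
non-identifiability warning for constant-input data.

## Cytometry channel

The synthetic cytometer draws log-normal FSC-H (median 40,000 a.u., log-sd
0.35), a tightly coupled FSC-A, a correlated SSC-A, and
`FL1 = FSC-H · (background + gain·G) · noise` with mean-one log-normal
noise (CV 0.25), so fluorescence scales with cell size and the expected
FL1/FSC-H equals `background + gain·G`. Gating applies the published
FSC-H (11,000 a.u.) and FL1 (800 a.f.u.) thresholds plus an elliptical
FSC-A×SSC-A gate whose exact instrument coefficients are not published; the
default ellipse retains ~75% of generated events (≈15,000 of 20,000),
consistent with the platform's throughput, and is fully configurable. The
scalar measurement is the sample mean of FL1/FSC-H divided by the
calibration-day un-induced baseline. The generator does not model
instrument compensation, multi-modal populations or autofluorescence
spectra; closed-loop scenarios default to an equivalent 3% multiplicative
noise on the fold change for speed, with the full event-cloud channel
available as a measurement mode.

## Disturbances

* **Medium shift** replaces `d_p` by `ln 2 / T_d(new)` at onset
  (M9→LB: 38 min → 25 min). In baseline-normalized coordinates this halves
  the attainable output level; restoring the pre-shift target would require
  an input beyond the dose-response range, so closed-loop runs recover only
  partially (they end far closer to target than frozen-input runs, which
  collapse to ~0.5× target). This saturation is a genuine consequence of
  the input-range and gain-scale choices above and is asserted as an
  ordering in the tests.
* **Temperature shift** scales transcription/translation/maturation rates
  by 0.46 and the dilution rate by 0.5, ramped linearly over 30 min. A
  *single* global scale was rejected: in fold-change coordinates it is a
  pure time rescaling that leaves the steady state unchanged, so a
  frozen-input culture would never drift out of band — contradicting the
  observed slow decline of uncontrolled cultures after cooling. The split
  (kinetics slowed slightly more than dilution) reproduces that decline;
  the post-shift dilution rate corresponds to a doubling time just above
  an hour.
* **Input offset** subtracts a fraction (default 50%) of the intensity in
  effect at onset from every later command, floored at zero.
* **Additive output** offsets the measurement only.
* **Day-to-day variability** applies independent median-preserving
  log-normal factors (sd 15%) to each rate and to the dose-response gain at
  culture start.

## Growth control

The turbidostat integrates `dx/dt = μx − (u_flow/V)x` at 1-s steps
(V = 17.5 ml, OD setpoint 0.1) under an inner PI loop tuned for a
~1-minute settling time; at regulation equilibrium the dilution rate equals
the growth rate, which is why the pump signal is a growth-rate sensor. The
estimator is a causal exponential moving average (5-min time constant) of
the 1 Hz pump samples divided by V, feeding the 1-min outer PI
(K_P = 6000, K_I = 45, integral clamped to [0, 60]). The MetE growth plant
is a first-order lag (τ = 45 min) toward a Hill-shaped steady-state map of
the green fraction (half-activation 30%, steepness 2), normalized so full
red gives exactly 0.0035 min⁻¹ and full green 0.0139 min⁻¹; the simplest
dynamics consistent with multi-hour settling and PI sufficiency. Optional
drift raises the red-light floor linearly (2e-6 min⁻² by default) after
12 h under predominantly red light, emulating the strain's gradual loss of
light sensitivity; the outer loop compensates, producing the characteristic
slow downward trend of the steady green input.

## Metrics conventions

Tolerance bands are ±5% of the target level (constant references), of the
instantaneous reference (sinusoids) or of the maximum reference level
(piecewise profiles). "Post-transient" starts at the first band entry
sustained for three consecutive samples, evaluated on the same signal being
scored (scoring the true output against a settling time detected on the
noisy measurement inflates the apparent early deviation). Sinusoid phase is
the lag maximizing the continuous cross-correlation with the reference,
computed by quadrature regression and reported in degrees in (−360, 360];
a half-period shift reads 180°. Plotted-curve smoothing (polynomial fits)
is presentation-only in the source material; all metrics here use raw
samples.

## Problem sizes and runtimes

Scenarios run 600–1440 simulated minutes (60–144 samples at 10-min
cadence; growth runs use 1-min updates with 60 inner steps each), the
particle filter 2000 particles, and the recovery study 20 seeds × 3 traces
× 60 samples; the full test suite completes in a couple of minutes on one
CPU. The batched ZOH discretization inside the filter uses a vectorized
scaling-and-squaring matrix exponential validated against scipy's `expm`.

## Limitations

Simulated cultures are means — no single-cell heterogeneity beyond the
cytometry event noise, no photocycle kinetics, no spatial light
attenuation, no autosampler hardware logic. The medium-shift recovery is
input-limited as described above. Passing the simulated suites demonstrates
the control and estimation machinery under the stated noise and
variability models, not wet-lab fluorescence magnitudes or day-specific
curves, which are intentionally out of scope.
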