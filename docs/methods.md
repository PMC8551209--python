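# Methods

## The plant: a basal-ganglia–thalamic network

The controlled system is a conductance-based network of four populations —
thalamus (TH), subthalamic nucleus (STN), external and internal globus
pallidus (GPe, GPi) — with ten single-compartment Hodgkin–Huxley neurons
each, in the Rubin–Terman / So-et-al tradition of reduced
basal-ganglia models.  Membrane dynamics per population are

    C_m dv/dt = −I_L − I_Na − I_K − I_T [− I_Ca − I_ahp] − I_syn + I_app (+ inputs),

with C_m = 1 µF/cm², the bracketed currents present in STN/GPe/GPi only,
and `I_app` the net bias current that encodes the condition: healthy
(STN 33, GPe 20, GPi 21 µA/cm²) versus Parkinsonian (23, 7, 15), standing
in for dopamine depletion.  TH additionally receives the sensorimotor
drive, the DBS control current, and (in one experiment) an ionic-channel
disturbance.  Gating kinetics and channel constants are transcribed from
the Rubin–Terman (2004) and So et al. (2012) model family; each synapse is
a first-order gate `ds/dt = α H(v_pre)(1−s) − β s` with a sigmoidal spike
detector `H`, rise α = 5 /ms (glutamatergic) or 2 /ms (GABAergic) and decay
β = 1 /ms and 0.08 /ms respectively.  Synaptic currents follow
`I = g (v_post − E) Σ_j s_j`.

Connectivity is deterministic and circular so runs are reproducible from a
seed alone: each GPe/GPi neuron receives two STN inputs (neighbours i±1)
and two GPe collaterals (i±2, never itself), each STN neuron two GPe
inputs (i±1), and GPi neuron *i* inhibits TH neuron *i* (a bijection).
In-/out-degrees match the published network; which particular neurons
connect is not specified there, so the circular scheme is a documented
choice.

The pallidal collateral terms enter the GPe/GPi membrane equations with a
minus sign like every other synaptic current; with `I = g (v−E) Σs` and
E = −85 mV a plus sign would make an inhibitory projection depolarizing.

### Sensorimotor drive

TH receives a shared train of rectangular pulses (amplitude 3.5 µA/cm²,
width 5 ms).  Each inter-pulse interval is the reciprocal of an
instantaneous rate drawn from a gamma distribution with mean 14 Hz and
coefficient of variation 0.2 (shape = 1/CV², scale = mean·CV²).  In the
healthy condition the TH population relays ≳ 90% of pulses (spike =
upward crossing of −20 mV within 10 ms of pulse onset); under the
Parkinsonian bias currents relay fidelity is reliably lower.  Relay
fidelity is scored per trial as the mean over the ten TH neurons.

### Integration

Fixed-step forward Euler at dt = 0.01 ms, the same step at which the
controller updates (zero-order hold, one controller evaluation per step).
Classical RK4 on the same grid is available (`method="rk4"`) and backs the
test oracles.  All state arrays carry a leading batch axis so independent
trials integrate simultaneously; per-step cost is dominated by numpy
dispatch, so batching ten trials costs nearly the same wall time as one.
Halving dt changes v_TH by well under 0.5 mV over tens of milliseconds;
over a full second, pointwise comparison at a fixed time is meaningless
for any integrator of this plant — sub-step shifts in spike timing
compound, and Euler vs RK4 at the same step disagree at the endpoint as
widely as Euler at dt vs dt/2.  Population statistics (rates, relay
fidelity, RMSE against a common reference) are the stable observables at
that horizon.

## The controller

The ten TH membrane potentials x are written as a first-order MIMO system
ẋ = f₁(x,t) + F₂(x,t)u + d(t) with unknown drift f₁ (which absorbs d),
input gain F₂ (physically 1/C_m · I), control u (the per-neuron DBS
current), and reference x_d = the healthy network's TH trace simulated
open loop with the same pulse train.  ẋ_d is the same-step finite
difference of that trace.  The tracking error is e = x_d − x.

* Sliding surface: `s_i = ∫ e_i dt + σ sig(e_i)^η` with σ = 0.1,
  η = 1.2 (sig(x)^p = |x|^p sign x).  The integral accumulates by the same
  forward-Euler rule as the plant.
* Reaching law: `ds/dt = −K₁ sig(s)^ρ₁ − K₂ sig(s)^ρ₂`,
  K₁ = I, K₂ = 1.5I, ρ₁ = 1.2, ρ₂ = 0.4.
* Equivalent control: `u_eq = F̂₂ᵀ(ε₀I + F̂₂F̂₂ᵀ)⁻¹ (−f̂₁ + ẋ_d +
  (1/ησ) sig(e)^{2−η} + K₁sig(s)^{ρ₁} + K₂sig(s)^{ρ₂})`, ε₀ = 0.01 — a
  regularized inverse that is always defined; with a well-conditioned F̂₂
  and small ε₀ it agrees with the exact-inverse law.
* Corrective term: `u_c = s |sᵀ| (ε̄_f1 + ε̄_f2|u_eq| + |u₀|) /
  (σ₀‖s‖² + Υ)` with σ₀ = 0.1, ε̄ = 0.1, and
  `u₀ = ε₀(ε₀I + F̂₂F̂₂ᵀ)⁻¹(· same bracket ·)`.  The outer product is read
  literally: u_c,i = s_i Σ_j |s_j| b_j / (σ₀‖s‖² + Υ).
* Υ adapts by `Υ̇ = −κ₀ |sᵀ| ησ diag(|e|^{η−1}) b / (σ₀‖s‖² + Υ)`,
  κ₀ = 0.1, Υ(0) = 1, clamped at 10⁻⁶ to preserve the strict positivity
  the denominator needs (the Υ → 0 limit is otherwise unhandled).
* Classical baseline (AFSMC): the same pipeline with η = 1, ρ₁ = 1 and
  ρ₂ = 0, where sig(s)⁰ := sign(s).  This discontinuity is the source of
  the baseline's chattering.

### Fuzzy estimator

f̂₁ (10-vector) and F̂₂ (10×10) are centre-average fuzzy systems over the
TH voltages with two Gaussian membership functions per input (centres
−49.59 and −25.36 mV, width 5 mV), chosen to span the operating range.
A full product rule base over ten inputs has 2¹⁰ rules; the default uses
the additive per-dimension activation (20 normalized rule strengths,
shared weights), which keeps the estimator desk-scale while remaining
linear in parameters; the product base stays available behind
`rule_base="product"`.  Weights start uniform in [0, 1] and adapt by the
Lyapunov-derived gradient laws

    ψ̇_f1[:, i] = −κ_f1 ξ(x) s_i ησ|e_i|^{η−1},
    ψ̇_f2[:, i, j] = −κ_f2 ξ(x) s_i ησ|e_i|^{η−1} u_eq,j,

κ_f1 = 3, κ_f2 = 1, projected onto |ψ| ≤ 10³ so they remain finite.  The
driving factor is exactly the surface Jacobian that appears in ṡ, so the
mismatch terms cancel in the Lyapunov derivative.

### Actuator saturation

The control current is clamped at |u| ≤ 200 µA/cm².  Two reasons.  First,
stability of the adaptive transient: the fuzzy weights start at random
values in [0, 1], and during the first milliseconds the regularized
pseudo-inverse can demand currents large enough to destabilize the
explicit integration; the clamp bounds that transient.  Second, the bound
is sized to the plant's own physics — the largest intrinsic membrane
currents of a (possibly heavily perturbed) relay cell are a few hundred
µA/cm², so 200 µA/cm² is enough authority to track through spike events
even under 50% parameter mismatch.  Tighter clamps (≤ 100 µA/cm²) make
some 50%-uncertainty draws untrackable: demand peaks saturate for
extended periods and the error grows by orders of magnitude, with large
trial-to-trial variance.  The default deliberately sits above that
cliff.

### Gains

The published experiments state that gains were hand-tuned but do not
print them.  The defaults in `ControllerConfig` are this repository's
frozen tuned set, found with the grid-search harness exposed as the
`tune` CLI command (objective: minimize nominal tracking RMSE subject to
the saturation bound) followed by a manual refinement of (η, ρ₂, u_max)
against the uncertainty scenarios; they are fixed across all experiments
and both controller modes, which differ only through (η, ρ₁, ρ₂).

## Experiments and metrics

Each trial: simulate the healthy reference open loop (1000 ms,
dt = 0.01 ms), then the PD plant in closed loop with the same pulse train.
Per-neuron RMSE `sqrt(mean |v_TH − v_THd|²)`, its mean over the ten
neurons, the energy index `sqrt(mean uᵀu)`, the time for |e₁| to fall and
stay below 1 mV for 1 ms, and a chattering index.  Scenario grid: nominal;
50% time-varying parameter uncertainty; uncertainty plus the
ionic-channel disturbance i_d(t) = sin(1 + k·t/10) µA/cm² on TH neuron k.
The disturbance time is interpreted in seconds — with t in ms the phase
would sweep three orders of magnitude faster than any channel process and
the ten neurons would receive essentially identical noise; the
seconds reading gives the population a slow phase gradient.  The formula's
source prints no unit; this is a documented choice (`t` in the code is ms
and is converted internally).

Uncertainty enters as an independent multiplicative trajectory on each of
23 parameters (six ionic conductances, five ionic reversal potentials, six
synaptic conductances, six synaptic reversals; one multiplier per symbol,
applied across populations, plant side only — the reference stays
nominal): uniform white noise through a fourth-order Butterworth low-pass
(cutoff 0.025 Hz, second-order sections), linearly interpolated onto a
1 ms grid and rescaled so the largest deviation within the simulated
window equals the requested level exactly.  At this cutoff the
trajectories are nearly constant within a single 1 s trial; each trial
therefore experiences an effectively static, trial-specific parameter
offset whose magnitude touches the level once.

Trials are batched (default ten per condition).  Reproducibility: one
master seed fans out through named `SeedSequence` substreams per trial
(pulse train, healthy initial voltages, PD initial voltages, fuzzy
weights, uncertainty), so any trial can be regenerated in isolation and
controller variants share identical inputs (paired comparisons).  The
healthy reference depends only on the seed and horizon and is computed
once per scenario pair.  Statistics: per-level one-way ANOVA between the
controllers on per-trial RMSE and Energy (pooled option available);
zero-variance cells are flagged, not tested.

### Chattering metric

Chattering is scored as the **median** per-step |Δu| after the first
50 ms, not the maximum: the maximum is dominated by the large, legitimate
control swings that accompany reference action potentials (ẋ_d moves by
tens of mV/ms between adjacent samples during a spike), which both
controllers exhibit equally.  The median isolates persistent switching
activity; under nominal conditions it separates the two laws by more than
two orders of magnitude.

## Numerical choices and edge cases

* `sig(·)^p` uses numpy power semantics, giving sig(0)^0 = 0 (no control
  action at exactly zero sliding variable in the classical limit).
* The settling-time bound for `V̇ ≤ −α₁V^λ₁ − α₂V^λ₂` is evaluated as
  `V₀^{1−λ₂}/(k a α₂) · ₂F₁(1, a; a+1; −(α₁/α₂)V₀^k)` with k = λ₁−λ₂,
  a = (1−λ₂)/k, which equals the exact time integral
  ∫₀^{V₀} dV/(α₁V^λ₁+α₂V^λ₂) in the equality case and reduces to the
  classical terminal settling time V₀^{1−λ₂}/(α₂(1−λ₂)) as α₁ → 0.
* Rule-strength underflow (inputs far outside the membership span) falls
  back to a uniform basis and logs a warning.
* Integration aborts with a step-stamped error on non-finite state;
  adaptation aborts on non-finite weights.
* The trace CSV stores full double precision; round-trips are lossless.

## Problem sizes

Default experiments use 1000 ms horizons at dt = 0.01 ms (10⁵ control
updates) with ten trials per condition, batched.  The test suite exercises
the same scenarios at four trials per condition, and uses short horizons
(30–200 ms) for step-convergence, trend and consistency checks; the
methods are identical, only the trial counts and horizons differ.

## What the synthetic conditions do and do not show

All inputs are generated by the model itself; there is no recorded data.
Passing experiments therefore demonstrate internal consistency of the
closed loop — the controller tracks a reference produced by the same
model family under the stated uncertainty and disturbances — not clinical
efficacy.  Known gaps between this testbed and real DBS: no extracellular
field or electrode geometry, monophasic unconstrained-charge stimulation,
a single fixed network size (10 neurons per population; other sizes run
but are untested), measurement is noise-free and instantaneous, and the
"healthy reference" would not be observable in a patient.
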