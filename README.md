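# dbsloop

A simulation testbed for **closed-loop deep brain stimulation (DBS)** in
Parkinson's disease: a conductance-based basal-ganglia–thalamic network
(thalamus, subthalamic nucleus, external/internal globus pallidus; ten
Hodgkin–Huxley neurons per population) whose Parkinsonian thalamus is driven
back onto the healthy firing pattern by a **MIMO adaptive fuzzy terminal
sliding-mode controller (AFTSMC)**, with the classical adaptive fuzzy
sliding-mode controller (AFSMC) as baseline.

Who it is for: researchers in computational neuroscience and control
engineering who want a reproducible, scriptable sandbox for closed-loop
neuromodulation algorithms — tracking-error and control-energy benchmarks,
robustness to time-varying parameter uncertainty, and disturbance rejection —
without any hardware or recorded data.

## The model and the control law

The Parkinsonian condition is a reduction of the net bias currents
(STN/GPe/GPi: 33/20/21 → 23/7/15 µA/cm²), which degrades the thalamic relay
of a stochastic sensorimotor pulse train (gamma-distributed instantaneous
rate, mean 14 Hz, CV 0.2).  The ten TH membrane potentials are cast as a
first-order MIMO system

    ẋ = f₁(x,t) + F₂(x,t) u + d(t),        e = x_d − x,

where x_d is the healthy network's TH trace under the same pulse train and
u is the per-neuron DBS current.  The controller drives e to zero in finite
time via the integral fractional-power sliding surface and two-power
reaching law

    sᵢ = ∫eᵢ dt + σ sig(eᵢ)^η,     ṡ = −K₁ sig(s)^ρ¹ − K₂ sig(s)^ρ²,

with the unknown dynamics estimated online by fuzzy systems f̂₁, F̂₂ (two
Gaussian membership functions per TH voltage, weights adapted by
Lyapunov-derived laws) inside a regularized equivalent control
u_eq = F̂₂ᵀ(ε₀I + F̂₂F̂₂ᵀ)⁻¹(·), plus a corrective term with an adaptive
denominator parameter Υ.  Setting η = 1, ρ₁ = 1, ρ₂ = 0 recovers the
classical AFSMC, whose sign(s) switching chatters.  See `docs/methods.md`
for the full account, all defaults, and the design decisions.

## Worked example

Run one nominal closed-loop trial (healthy reference vs controlled PD
plant, 1000 ms at dt = 0.01 ms):

```sh
dbsloop closedloop --mode aftsmc --seed 1 --trials 1 --out out/nominal
```

which prints

```
trial 0: RMSE(neuron 1) = 0.107 mV, mean RMSE = 0.116 mV, energy = 46.6 uA/cm^2, converged in 1.31 ms
```

— the PD thalamic trace tracks the healthy reference to about a tenth of a
millivolt, the membrane potential enters the ±1 mV band around the
reference within about a millisecond of loop closure, and the stimulation
effort (RMS of the 10-channel control vector) is ~47 µA/cm².
`out/nominal/` contains the effective configuration, per-trial metrics and
a tracking figure.  Other entry points:

```sh
dbsloop simulate  --condition pd --seed 1        # open loop, relay fidelity
dbsloop compare   --uncertainty 0.5 --trials 10  # AFTSMC vs AFSMC + ANOVA
dbsloop sweep     --levels 0,0.25,0.5 --trials 10 --disturbance
dbsloop tune                                     # gain-search harness
```

Everything is reproducible: one master seed fans out to named substreams
(pulse train, initial voltages, fuzzy weights, uncertainty draws), so any
figure in `out/` is regenerable from its `effective_config.yaml` + seed.

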