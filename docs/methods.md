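# Methods

`pelvimon` is a software digital twin of an intraoperative pelvic
neuromonitoring method in which pelvic autonomic nerves are identified by
stimulating them directly and reading out the resulting smooth-muscle
contraction of the bladder or rectum as a change in tissue impedance.  The
package simulates every stage of that measurement — contraction dynamics,
the tissue equivalent circuit, the analog measurement chain, lock-in
demodulation, and trace analytics — so that the signal-processing chain and
the evaluation protocol can be studied, stress-tested and extended without
an animal on the table.  This note documents the models, the defaults, and
the reasoning behind the genuinely open design choices.

## Recruitment model

A stimulation pulse train (monophasic rectangular pulses; amplitude
`I` in mA, rate `f` in Hz, width fixed at 1000 µs) recruits a fraction
`r(I, f) ∈ [0, 1]` of the excitable fibers reaching the target organ:

* **Amplitude**: zero at or below `threshold_current` (default 5 mA),
  linear up to `saturation_current` (default 30 mA), then saturated.
  Fibers fire when their excitation threshold is exceeded; a linear ramp is
  the simplest recruitment curve consistent with a distributed threshold
  population.
* **Frequency**: unimodal tuning with its maximum at `freq_peak`
  (default 30 Hz).  The tuning is a two-sided Gaussian: width
  `freq_bandwidth` (default 20 Hz) below the peak and
  `freq_bandwidth × high_side_ratio` (default ratio 0.5) above it.  The
  asymmetry is deliberate: autonomic transmission follows moderate pulse
  rates but fails at high rates, and the observed response ordering is
  30 Hz > 10 Hz > 50 Hz — a symmetric tuning centred at 30 Hz would tie
  10 and 50 Hz, contradicting that ordering.  With the defaults,
  `r(15 mA, ·)` evaluates to 0.40 at 30 Hz, 0.24 at 10 Hz and 0.05 at
  50 Hz.
* **Site**: fixed-landmark sites (vesicouterine ligament, paraproctium,
  direct organ stimulation) have multiplier 1.0; the handheld plexus probe
  defaults to 0.8 (position-dependent); the wound margin is 0 — it is the
  negative control and must recruit nothing.

Strength–duration (chronaxie) behavior is not modelled: pulse width is
never varied in the protocols of interest.

## Contraction dynamics

Activation `c(t) ∈ [0, 1]` follows piecewise first-order kinetics,
integrated by exact exponential updates on a fixed 100 Hz control grid
(the system is stiff-free and the update is deterministic):

* during stimulation, `c` relaxes toward the drive `r·q` with time
  constant `tau_act` (default 10 s) — the slow, seconds-scale rise of the
  visceral "slow wave" response;
* during rest, `c` decays with `tau_rel` (default 30 s), so a two-minute
  rest leaves `e⁻⁴ ≈ 2%` of the peak — complete relaxation on the
  protocol's timescale;
* a recovery pool `q ∈ [0, 1]` (contractile capability) depletes while
  the muscle is contracted, `dq/dt ⊃ −c·q/tau_deplete`
  (`tau_deplete` = 70 s), and is replenished in proportion to how relaxed
  the muscle is, `dq/dt ⊃ (1−c)·(1−q)/tau_recover`
  (`tau_recover` = 40 s).

The pool reproduces the memory effect that motivates the protocol design:
restimulation after a full two-minute rest reaches the previous peak
(within 2%), whereas restimulation after only 30 s falls short
(peak₂/peak₁ ≈ 0.94 at the default drive).  The relaxation gate on
recovery matters: with an ungated, always-on recovery term no depletion
constant satisfies both of those behaviors simultaneously — recovery during
the short rest is then too effective relative to the long rest.  Gating by
`(1−c)` is also the physiologically sensible choice (metabolic recovery
proceeds when the muscle is not working).  `tau_act` and `tau_rel` are the
directly protocol-visible constants; none of the four is a measured
quantity, and all are configurable.

**Spontaneous activity.**  The rectum (not the bladder) superimposes
bounded sinusoidal self-activity on `c`: amplitude 0.07 (about 20% of the
default stimulated peak), frequency 0.1 Hz, seeded random phase, with a
soft start over half a period so the pre-recording reference state is
exactly baseline.  It is *not* subtracted anywhere downstream — it appears
in the normalized trace exactly as it does on the real monitor, and the
event detector must be parameterized above it (see below).

**Negative controls.**  `nerve_intact=False` zeroes the stimulated
component of `c` (self-activity may remain for the rectum).  The
`vecuronium` flag exists because a skeletal-muscle relaxant is a standard
confounder check: it changes nothing in the smooth-muscle dynamics, and the
simulator guarantees bit-identical trajectories with the flag on or off at
the same seed.

## Tissue equivalent circuit

The organ between the measurement electrodes is a Fricke-type equivalent
circuit: series resistance `Rs` (extracellular path, default 150 Ω) plus a
parallel branch `Rm ∥ Cm` (membranes; defaults 200 Ω, 0.5 µF).  At the
default 1007 Hz carrier this gives |Z| ≈ 306 Ω and phase ≈ −17°
(capacitive).  Contraction compresses the tissue's layered structure and
displaces fluid, changing both resistive and capacitive properties; the
model scales the resistances by `(1 + k_r·g·c)` and the capacitive
reactance by `(1 + k_c·g·c)`, where `g` is the electrode coverage
fraction.  With the default couplings `k_r = k_c = 0.1` the whole
impedance scales by `(1 + 0.1·g·c)`: +10% magnitude at full contraction
under full coverage, impedance strictly rising with contraction, phase
unchanged.  The magnitude of the change is not a measured number — only
its sign (impedance rises during contraction) is fixed; the default is
configurable.

Electrode setups: tetrapolar (four-electrode, hardware version one)
measurements exclude electrode contact impedance; bipolar (two-electrode,
version two) measurements add `2 × contact_impedance` (default 100 Ω per
electrode) as a contraction-independent series term, which dilutes the
relative change.  Observability scales linearly with `coverage`
(fraction of contractile muscle between the electrodes); zero coverage
hides the contraction entirely even though the muscle contracts — the
known failure mode of poor electrode placement.  The five named setups
(two bladder, three rectum) carry qualitative coverage and
coverage-variability defaults: needle-only placements are steadier (low
inter-individual spread) than mixed surface/needle ones.

## Measurement chain

A 50 µA sine test current at the carrier frequency is driven through the
tissue; the voltage drop is amplified (gain 50) and high-pass filtered
(160 Hz, 2nd-order Butterworth) before demodulation.  The carrier
frequency is an instrument design choice, not a stated quantity: the
default 1007 Hz sits above the high-pass cutoff, two decades above the
5 Hz post-demodulation low-pass, and — being prime — off the 10–50 Hz
stimulation harmonic grid, so no pulse harmonic lands inside the lock-in
passband.  Impedance varies orders of magnitude slower than the carrier,
so synthesis uses the quasi-static envelope
`v(t) = i_test·|Z(t)|·sin(ωt + θ(t))`.

Additional input terms: white Gaussian noise (default 0.15 mV rms
referred to the input, about 1% of the nominal 15.3 mV carrier) and
stimulation crosstalk, modelled as the attenuated pulse train added at the
input with coupling `crosstalk_coupling` volts per mA (default 10⁻⁴).
Crosstalk is rejected twice: the high-pass removes the pulse train's
low-frequency content, and the lock-in passband only admits the ±5 Hz
neighbourhood of the carrier, where the nearest pulse harmonics (990 and
1020 Hz for 30 Hz trains) are strongly attenuated by the 3rd-order
low-pass.  The measured baseline shift from a 15 mA/30 Hz leak is far
below 1%.

Filters are applied causally (forward-only), as the analog hardware does.
The settling transient of the 5 Hz low-pass (taken as 3/cutoff = 0.6 s) is
part of the signal; baseline windows must start after it, and the pipeline
prepends a rest lead-in so the baseline window never touches the
transient.  Sampling is 20 kHz into a 16-bit ±5 V ADC (instrument-typical
values).  Note the ADC range is sized for the default tissue circuit
(baseline output ≈ 4.2 V); driving the chain with a 1 kΩ load at default
gains exceeds ±5 V and clips, as a real front end would.

## Lock-in demodulation

**Version one** multiplies by a single sine reference and integrates
through the 3rd-order 5 Hz low-pass, then applies the DC gain of 11.  For
a carrier `A·sin(ωt+θ)` the settled output is `U = 11·(A/2)·cos(θ − ref)`.
The reference phase is set by calibration (`calibrate_phase_v1`), which
emulates the hardware potentiometer: maximize the baseline output over a
1° grid, refine to 0.1°.  Because the v1 output is exactly a cosine in the
reference phase, the sweep is evaluated analytically from a single I/Q
demodulation of the baseline — identical result, hundreds of times faster.

**Version two** multiplies by sine and cosine references, demodulates and
digitizes each branch, and vector-sums the ADC outputs:
`U = 11·A/2` independent of phase, with `phase_est = −θ` (a capacitive,
negative tissue phase is displayed as a positive lag; the sign convention
is part of the API contract).  Where the magnitude is below 10 ADC steps
the phase is meaningless and flagged invalid.  The hardware alternates the
two references; the default implementation multiplies both branches
continuously (equivalent in steady state), and a chopped mode with
configurable alternation rate is provided for fidelity studies.

**Chain phase compensation.**  The causal 160 Hz high-pass leads the
carrier by a small, design-determined phase (≈ +13° at 1007 Hz).  For
recordings flagged as chain-filtered, both demodulators offset their
references by this known value (computed from the designed filter
response), so calibrated and estimated phases refer to the *tissue*.  Bare
synthetic carriers bypass the chain and satisfy the closed forms exactly.
Demodulated output is decimated to 100 Hz for storage; the post-low-pass
bandwidth (5 Hz) is far below the decimated Nyquist, so no aliasing.

## Trace analytics

The absolute impedance depends on electrode placement and contact and
carries no information; the monitor trace is therefore normalized to its
pre-contraction baseline, `u(t) = U(t)/U(0)`, with `U(0)` the mean over
the 5 s immediately preceding the first stimulation.  Normalization fails
loudly when the baseline is below 10× its own noise floor (lost contact).
`u` is invariant to any overall gain change by construction.

**Per-phase metrics**: peak `u` within each stimulation phase plus a 10 s
grace period (the low-pass delays the displayed peak), `delta_u = peak − 1`,
time to peak, and the residual `|u − 1|` at the end of the following rest.

**Event detection** is a Schmitt trigger: an event requires `u − 1` to
exceed `max(k·σ, min_delta)` (onset, default k = 5 baseline noise sigmas)
continuously for ≥ 2 s, and extends over the surrounding span where
`u − 1` stays above `k_end·σ` (release, default k_end = 2).  The
hysteresis exists because the contraction tail relaxes with a 30 s time
constant and therefore hovers near any single threshold for many seconds,
where noise would otherwise shed spurious fragment events; sub-duration
crossings never seed an event, and events closer than 1 s merge.  For the
rectum the pipeline raises the onset floor (`min_delta`) to 1.5× the
self-activity amplitude in `u` units, since spontaneous activity is not
subtracted.

**Artifact flagging**: mechanical manipulation produces step-like jumps
far steeper than any contraction.  Samples whose slope exceeds a limit —
10× the steepest physiological slope `U0·coupling·coverage/tau_act`, but
never below 8× the slope noise floor measured on the baseline — are
flagged (±0.1 s padding) and excluded from metrics.  Slope is the only
discriminator; the physiological and mechanical signatures differ in more
ways, but slope is the rule that is simple, parameter-light and testable.

**Manometry reference**: `p(t)/p(0) = 1 + gain·c(t)` (default gain 0.3)
plus white noise (default 0.003), *only* when the bladder holds at least
50 ml; an empty bladder transmits no pressure regardless of contraction.
This reproduces the operational asymmetry that motivates the impedance
method: pressure needs a 150 ml fill, impedance does not.

**Condition statistics**: arithmetic mean, median, linearly interpolated
quartiles and Tukey whiskers (1.5×IQR, clamped to observed data), pooling
all stimulation phases of all trials and reporting n.  Cohort simulations
draw per-trial effective coverage from a lognormal distribution with the
setup's coefficient of variation — electrode placement varies between
individuals, and this is the dominant source of the across-animal
dispersion the box plots summarize.

## Reproducibility

All randomness flows from one global seed through named sub-streams
(`contraction`, `noise`, `manometry`, `trial{i}`, …) derived via CRC32 of
the stream name, so adding a new noise source never perturbs existing
streams, and identical config + seed gives bit-identical outputs.  Traces
serialize to CSV (12 significant digits) with JSON sidecars carrying the
chain config and seed; run bundles include a config snapshot, its hash and
per-stage timings.

## Problem sizes

The reference run is the full protocol — a rest lead-in plus
3 × (30 s stimulation + 120 s rest) ≈ 457 s — synthesized at the full
20 kHz chain rate (≈ 9.1 M raw samples) and analyzed at 100 Hz.  Cohort
studies use 20 trials per condition for frequency comparisons and 100
seeds per negative-control condition in the test suite; the acceptance
script uses 10 trials and 25 seeds per condition, which is ample for the
orderings and rates it reports.

## Limitations

* No spatial or 3-D tissue model, no action-potential-level neuron model,
  no motor (CMAP) pathway: the twin operates at the level of lumped
  recruitment and lumped contraction.
* Contraction kinetics, impedance-change magnitude and self-activity
  parameters are plausible configurable defaults, not measured claims; the
  package reproduces the *qualitative* behaviors (directions, orderings,
  memory effects, control silences), and passing tests certify the chain
  and analytics, not quantitative physiology.
* The front end is ideal apart from white noise, crosstalk and ADC
  quantization: no offset drift, slew, electrode polarization
  electrochemistry, or mains interference (generic interference can be
  injected through the noise/crosstalk hooks).
* Artifact discrimination is slope-only and will miss slow drifts (e.g.
  gradual electrode migration).
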