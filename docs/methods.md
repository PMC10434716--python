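# Methods

## The model

`visfield` implements a stochastic dynamic neural field model of the
visibility of low-contrast line segments.  A one-dimensional excitatory
activation field `u(x, t)` represents a retinotopic map of line-segment
detectors; localized stimulus input `S(x)` (a Gaussian bump whose peak is
the "stimulus-initiated activation" of a given Michelson contrast) drives
the field, and a companion inhibitory field `v(x, t)` provides recurrent
inhibition.  Activation above zero at a stimulus location is read out as
"the stimulus is visible there".  The dynamics are

    tau_u du = [ -u + h_u + n(t) + g_m * m + S*(1 - g_a * a)
                 + k_uu * f(u) - k_uv * f(v) ] dt + fast noise
    tau_v dv = [ -v + h_v + k_vu * f(u) ] dt

with `f` a logistic sigmoid (steepness `beta`, value 0.5 at threshold),
`k_**` integral-normalized Gaussian kernels, and `*` spatial convolution.

Two slow variables are gated by *regional* suprathreshold activity — the
region where a wide Gaussian smoothing (`trace_spread_width`, 20 field
units ≈ 16.5 arcmin) of the suprathreshold indicator `1[u > 0]` exceeds a
small fixed level:

* **memory trace** `m(x)`: relaxes toward 1 inside the region with
  `trace_build_tau` (0.5 s) and decays outside with `trace_decay_tau`
  (5 s).  Through the resting-level boost `g_m * m` it preactivates the
  neighborhood of recently visible stimulation — the mechanism that
  bridges blank intervals and links successive presentations at
  unpredictable nearby locations.  Because it saturates within roughly one
  presentation, repeating a visible stimulus adds little further trace.
* **adaptation** `a(x)`: relaxes toward 1 inside the same region but with
  a much slower time constant (`adapt_tau`, 10 s), and weakens stimulus
  input multiplicatively (`S * (1 - g_a * a)`, clipped at zero).  Only
  *visible* (suprathreshold) episodes adapt; subthreshold episodes leave
  no adaptation — the model's adaptation asymmetry.  Because it integrates
  slowly, repeated visible presentations accumulate adaptation roughly
  linearly.

The trace/adaptation asymmetry — fast-saturating facilitation versus
slowly-integrating suppression over the same spatial region — is what
makes start-of-trial repetitions reduce subsequent visibility (their extra
adaptation outweighs their negligible extra trace) while a single
presentation still strongly facilitates a probe shortly afterwards.

Stochasticity has two components: a spatially uniform resting-level offset
`n(t)` following an Ornstein–Uhlenbeck process with a 16-s time constant
(emulating slow drift of an observer's sensitivity across trials) and weak
fast white noise per grid point.  Initial `n` for each trial is drawn from
its stationary distribution.

### Why these mechanisms produce the observed phenomenology

Self-excitation (`k_uu`) makes detection a subcritical instability: over a
band of input amplitudes both a subthreshold state and a self-excited
suprathreshold peak are stable.  The calibrated band is ≈ [4.10, 4.60] on
the input-amplitude scale, strictly inside the contrast ladder (3.8–5.4).
An object at amplitude 4.7 sits just above the deterministic detection
instability, so slow-noise drift makes initial detection bistable (≈ 62/38
split), while the band width plus the regional trace make the established
state resistant to drift — the low per-relocation switch probability
(≈ 0.04 per presentation in both directions).

Recurrent inhibition is engaged only when the suprathreshold bump is wide
enough to push the inhibitory field over its deep threshold: that holds
for the amplitude-10 high-contrast object but not for the amplitude-5
low-contrast object across the operating range of `n`.  Hence a
low-contrast object facilitates detection of a probe 8 field units away
(excitatory kernel tail plus trace), while a high-contrast object
suppresses it (wide inhibitory kernel).

## Spatial and stimulus calibration

* 8 field units = 6.6 arcmin (the printed center-to-center object–probe
  distance), i.e. 1.2121 units/arcmin.
* Grid: 201 points at 1-unit spacing (±100 units), open boundaries with
  zero-padded convolution.
* Contrast → amplitude: linear between the ladder anchors 0.008 ↦ 3.8 and
  0.073 ↦ 5.4, with the printed per-stimulus overrides (low-contrast
  object 5.0, high-contrast object 10.0, brief probe 4.5, constant
  object 4.7) taking precedence.
* Relocations: each presentation appears at an independent uniform
  location in a ±12.8-arcmin square (doubled for the brief-frame design).
  The 2-D sequence is mapped to the 1-D field by applying the Euclidean
  consecutive distance with a random sign, reflected at the window edges.
  Under this uniform rule the exact mean consecutive distance is
  0.52141 × 25.6 ≈ 13.4 arcmin; the tests assert this closed-form value.

## The model observer

A stimulus frame is scored visible when `u` exceeds zero within half an
input width of the stimulus center for at least 25% of the frame's sampled
instants (5-ms sampling).  The sustained criterion avoids counting
transient noise spikes as percepts; activation exactly at zero counts as
invisible.  Which stimulus is judged follows the task instructions of each
design: the probe in the pair and threshold designs, the object in the
relocation designs.  Switch statistics are derived from the per-frame
boolean sequence (blank frames excluded).

Hysteresis analyses use the study's asymmetric conventions: ascending
trials are filtered to those starting invisible and contribute the
proportion with at least one invisible→visible switch; descending trials
are filtered to those starting visible and contribute the proportion
remaining visible throughout; the gap is compared on the end contrasts
common to both directions (0.017–0.065).  SEMs are computed over eight
pseudo-subject blocks, mirroring the eight-observer error bars of the
human panels; no ANOVA-style inference is computed.

## Numerical choices

* Explicit Euler–Maruyama, `dt` = 1 ms (≤ tau/10 for all fields), noise
  scaled with sqrt(dt).  The compiled integrator and the plain-numpy
  reference `step()` agree to machine precision in the noise-free case
  (tested).
* Gaussian kernels truncated at four widths; convolution is zero-padded
  (open field boundaries).
* Stationary-state analysis freezes trace and adaptation at zero, turns
  noise off, and relaxes from (i) the resting state and (ii) a pre-formed
  suprathreshold peak; attractors are classified by peak `u` against zero
  and deemed distinct when peaks differ by more than 1e-4.
* Ties at exactly `u = 0` are classified invisible (fixed convention).
* Per-trial randomness comes from seeds bound deterministically to
  (master seed, experiment, cell index, trial index), so results are
  independent of execution order; bit-identical reproduction is guaranteed
  within this implementation, not across RNG families.

## Parameters

All ten experiment simulations share the single parameter set in
`src/visfield/config/default_params.yaml`.  The exact coupling constants
are not printed in the source material available to this package, so they
were calibrated once, in this order, and then frozen: (1) the bistable
input band must lie strictly inside the contrast ladder; (2) the initial
614-ms presentation of the amplitude-4.7 object is detected on ~62% of
trials; (3) the fitted per-relocation switch probability is near 0.04 in
both directions; (4) the amplitude-5.0 object facilitates and the
amplitude-10.0 object suppresses a neighboring probe.  Time constants:
excitation 20 ms, inhibition 10 ms, trace build 0.5 s / decay 5 s,
adaptation 10 s, slow noise 16 s.  The deep inhibitory resting level
combined with a strong inhibitory gain implements the contrast dependence
of facilitation vs. suppression.

## What the synthetic protocols do and do not emulate

The stimulus generators reproduce the printed frame schedules (614-ms
first frames, 360-ms relocations, 116-ms brief frames, 107-ms probes,
614-ms blanks), contrast ladders (0.008 steps), repetition manipulations,
and randomized relocation geometry.  They do not render luminance images:
the marker and the black flanker of the human experiments are attention /
position cues and are deliberately not modeled as field inputs, so
"baseline" trials are probe-only.  Consequences of eye movements,
attention, learning, and session structure are outside the model; passing
tests show that the field dynamics reproduce the detection statistics
under the stated input mapping, not that these other factors are
negligible in human data.

## Known limitations

* At the lowest probe contrast (0.008) the low-contrast-object condition
  can fall marginally below baseline: the rare baseline detections there
  require extreme resting-level offsets, at which the object partially
  engages inhibition.  (The source model likewise underestimates
  visibility at the lowest contrasts.)
* The simulated visible→invisible switch hazard rises with presentation
  number (adaptation accumulates over a trial) rather than staying
  constant; the one-parameter constant-hazard fit still recovers a
  per-presentation probability near 0.04.
* The 1-D reduction preserves inter-location distances only pairwise along
  the relocation chain, not the full 2-D configuration.
* The printed mean relocation distance (14.3 arcmin) is not exactly
  reproducible from the printed uniform-window sampling rule (which gives
  13.4 arcmin); the generators implement the rule, not the printed mean.
* Monte-Carlo sizes in the test suite (40–200 trials per design cell) are
  chosen to keep the full suite within a desk-scale run; the acceptance
  script uses 200 trials per presentation count (1,600 trials) for the
  headline statistics.
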