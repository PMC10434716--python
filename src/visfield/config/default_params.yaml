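# Calibrated single parameter set shared by every experiment simulation.
# Time constants in ms, spatial widths in field units (8 units = 6.6 arcmin),
# amplitudes in activation units relative to the zero visibility threshold.
#
# Calibration order: bistable input band inside the contrast ladder
# (3.8-5.4) -> 62/38 initial-detection split at amplitude 4.7 -> per-
# relocation switch probability near 0.04 -> facilitation/suppression
# crossover between the amplitude-5.0 and amplitude-10.0 objects.
field:
  tau_u: 20.0          # excitatory time constant
  tau_v: 10.0          # inhibitory time constant
  h_u: -5.18           # excitatory resting level (below threshold)
  h_v: -4.7            # inhibitory resting level (deep: engaged by strong input)
  beta: 4.0            # sigmoid steepness
  w_uu_amp: 5.5        # self-excitation strength
  w_uu_width: 3.8
  w_uv_amp: 40.0       # inhibition onto the excitatory field
  w_uv_width: 10.0
  w_vu_amp: 8.0        # excitatory drive onto the inhibitory field
  w_vu_width: 5.0
  input_width: 3.0     # spatial width of a line-segment input
trace:
  trace_build_tau: 500.0
  trace_decay_tau: 5000.0
  trace_gain: 0.9
  trace_spread_width: 20.0   # regional preactivation around visible stimuli
adaptation:
  adapt_tau: 10000.0
  adapt_gain: 1.1
noise:
  noise_slow_tau: 16000.0  # slow resting-level drift (trial-to-trial sensitivity)
  noise_slow_amp: 0.38     # stationary SD of the slow offset
  noise_fast_amp: 0.15     # fast per-detector fluctuation
integration:
  dt: 1.0
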