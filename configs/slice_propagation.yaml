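# Disinhibited slice propagation experiment: CA3-side stimulus, anisotropic
# axonal geometry, 1.5 x 1.5 mm grid of 100 um mean-field compartments.
slice:
  no_inhibition: true
  stim_ix: 1
  stim_iy: 7
  stim_amplitude_hz: 40.0
  duration_ms: 300.0
drive:
  kind: constant
  nu0_hz: 0.0
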