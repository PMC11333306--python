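# Desk-scale validation circuit: one fifth of the full CA1 microcircuit
# (convergences scale with the sizes; probabilities stay at their
# published values).
network:
  n_pyr: 1000
  n_fs: 100
  n_ext: 1000
drive:
  kind: constant
  nu0_hz: 5.0
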