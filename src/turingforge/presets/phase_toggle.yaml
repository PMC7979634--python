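# Static spatial C step (0 -> 2 across x = 60) while a toggles between 1 and
# 6 every 3000 time units, flipping the v pattern between in and out of phase.
seed: 0
kinetics: {family: phase_switching, a: 1.0, b: 1.0}
stability: {D: 50.0}
simulation:
  dimensions: 2
  Lx: 120.0
  Ly: 60.0
  nx: 192
  ny: 96
  t_min: 5900.0
  t_cap: 11800.0
fields:
  steps:
    - {param: C, axis: x, center: 60.0, width: 1.0, low: 0.0, high: 2.0}
  square_waves:
    - {param: a, period: 6000.0, high: 6.0, low: 1.0}
output: {directory: out_phase_toggle}
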