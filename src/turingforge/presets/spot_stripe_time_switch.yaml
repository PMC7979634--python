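# 120x60 domain, half in a spot regime and half in a stripe regime via a
# tanh step in C centred at x = 60, with the two halves swapping every 3000
# time units (square-wave clock of period 6000).
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
  square_waves:
    - param: C
      period: 6000.0
      high: {axis: x, center: 60.0, width: 1.0, low: 0.0, high: 1.0}
      low: {axis: x, center: 60.0, width: 1.0, low: 1.0, high: 0.0}
output: {directory: out_time_switch}
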