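# Same system on a domain just below Lc: no mode fits and the final state
# stays homogeneous.
seed: 0
kinetics: {family: circle, a: 0.0, b: 0.0}
stability: {D: 8.0}
simulation:
  dimensions: 1
  L: 3.7
  nx: 256
  t_min: 10000.0
output: {directory: out_mode1_below}
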