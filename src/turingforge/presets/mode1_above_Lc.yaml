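# 1D run of the disc system at its marginal centre (a=b=0) on a domain just
# above the minimum length Lc ~ 3.77: a single boundary peak (mode 1) forms.
seed: 0
kinetics: {family: circle, a: 0.0, b: 0.0}
stability: {D: 8.0}
simulation:
  dimensions: 1
  L: 3.8
  nx: 256
  t_min: 10000.0
output: {directory: out_mode1_above}
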