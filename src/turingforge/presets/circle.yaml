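# Linear analysis of the unit-disc Turing space S = 1 - a^2 - b^2
# (direct parameterization F = 2 - a^2, G = 1 + b^2).
seed: 0
stability:
  region: circle
  radius: 1.0
  D: 8.0
  resolution: 401
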