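# Linear analysis of the two-branch region (a-3)^2 - b^2 >= 1, 0<=a<=6:
# pure kinetics on the a<3 branch, cross kinetics on the a>3 branch.
seed: 0
stability:
  region: two_branch
  a_max: 6.0
  b_max: 6.0
  D: 50.0
  resolution: 401
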