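# Preserve a detailed prepattern in the image centre: the steady state U(x)
# is scaled inversely with intensity from 1 (white) to 11 (black); S = -1
# and a large cubic C = 20 pin u to U(x) inside, while S = 1 outside drives
# spots (white, C=0) and a labyrinthine ring (grey, C=2).
seed: 0
kinetics: {family: steady_state, S: 1.0, U: 1.0, V: 1.0}
stability: {D: 20.0}
simulation: {dimensions: 2, Lx: 96.0, Ly: 96.0, nx: 96, ny: 96, t_min: 2000.0}
fields:
  image: centre.png
  n_levels: 3
  thresholds: [64, 192]
  mapping: preserved_centre
  steady_state_image: centre.png
  U_low: 1.0
  U_high: 11.0
output: {directory: out_preserved}
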