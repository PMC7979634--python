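# Segment a grayscale image into three intensity classes and map them to
# kinetic parameters: spots in the black region (C=1, a=1), stripes in the
# white region (C=0, a=1), inverted patterns in the grey region (C=0.4, a=6).
# Generate the synthetic fixture first:
#   turingforge fixtures shapes.json prepattern.png
seed: 0
kinetics: {family: phase_switching, a: 1.0, b: 1.0}
stability: {D: 50.0}
simulation: {dimensions: 2, Lx: 96.0, Ly: 96.0, nx: 96, ny: 96, t_min: 2000.0}
fields:
  image: prepattern.png
  n_levels: 3
  thresholds: [64, 192]
  mapping: spot_stripe_inverse
output: {directory: out_image}
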