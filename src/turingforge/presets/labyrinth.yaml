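# Same linear problem with a dominant cubic term C = 2: stripes/labyrinth.
seed: 0
kinetics: {family: cross, S: 1.0, C: 2.0}
stability: {D: 9.0}
simulation: {dimensions: 2, L: 50.0, nx: 96, ny: 96, t_min: 2000.0}
output: {directory: out_labyrinth}
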