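# Phase-switching family at (a, b) = (6, 1): cross kinetics, out-of-phase spots.
seed: 0
kinetics: {family: phase_switching, a: 6.0, b: 1.0}
stability: {D: 50.0}
simulation: {dimensions: 2, L: 50.0, nx: 128, ny: 128, t_min: 2000.0}
output: {directory: out_phase_out}
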