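# Default toy crystal and simulation settings for the CLI examples.
[structure]
seed = 1
n_atoms = 40
d_min = 2.5

[simulation]
seed = 1
n_patterns = 200
observed_fraction = 0.15
partiality_min = 0.1
scale_sigma = 0.4
noise_background = 25.0
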