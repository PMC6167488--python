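site	conformer	activation_energy_kj_mol
omega	1	54.70
omega_prime	1	56.62
omega_dblprime	1	59.44
omega-1	1	36.17
omega-2R	1	42.91
omega-2S	1	42.46
omega-3R	1	45.13
omega-3S	1	44.94
omega	2	51.78
omega-1	2	35.48
omega-2R	2	37.56
omega-2S	2	37.90
omega-3R	2	36.54
omega-3S	2	39.50
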