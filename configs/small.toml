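# Desk-scale smoke configuration: a 300-kb arm that runs `all` in seconds.
seed = 42

[simulate]
arm_length = 300000
n_genes = 30
n_gaps = 10
n_markers = 8
n_qtls = 4
te_fraction = 0.5
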