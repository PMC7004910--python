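# Standard study arm: 5 Mb, 200 genes, 100 planted gaps (the generator
# defaults, written out for visibility).  `armcompare all --config
# configs/default.toml` takes a few minutes on one CPU.
seed = 42

[simulate]
arm_length = 5000000
n_genes = 200
n_gaps = 100
te_fraction = 0.55
subst_rate_neutral = 0.05
loss_prob = 0.03
reloc_prob = 0.03

[gapfill]
flank_len = 1500
min_hit_identity = 0.95
min_hit_len = 200

[orthology]
min_identity = 0.70
min_query_coverage = 0.50
bin_size = 500000

[date_ltr]
rate = 1.3e-8

[anchor]
max_mismatch = 1
three_prime_exact = 3
link_window = 3000000
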