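cross	genotype_class	observed	expected_weight
NTAP	wild_type	25	1
NTAP	heterozygous	47	2
NTAP	homozygous	1	1
NSC	wild_type	41	1
NSC	heterozygous	82	2
NSC	homozygous	25	1
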