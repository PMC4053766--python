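rna_class	hek293_srna_18_30	hela_ago2ip_async	hela_ago2ip_mitotic
miRNA	18.304	89.750	82.237
tRNA	9.694	0.204	0.298
snRNA	5.275	0.029	0.071
CD_snoRNA	1.751	0.005	0.054
HACA_snoRNA	0.318	0.026	0.046
none	64.658	9.985	17.293
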