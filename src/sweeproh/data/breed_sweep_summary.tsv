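breed	raw_regions	filtered_regions	novel_genes	known_genes	mean_mu	sd_mu
Ankole	33864	106	13	93	1.75e-11	1.33e-11
Karamojong	33631	138	16	122	1.49e-11	1.07e-11
Nganda10	32249	370	40	330	1.19	0.676
Nganda17	33876	101	7	94	1.94e-11	1.54e-11
Nkedi	33907	91	9	82	1.92e-11	1.59e-11
Ntuku	33904	89	7	82	1.87e-11	1.29e-11
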