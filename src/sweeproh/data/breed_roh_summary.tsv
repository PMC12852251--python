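breed	n_animals	n_roh	snps_in_roh	snps_in_roh_pct	froh_mean	froh_sd	threshold	conserved_segments	candidate_genes	mean_size_kb	sd_size_kb	novel_genes
Ankole	19	2938	6028475	51.1	0.052	0.014	0.60	12	3	1732.19	726.6	1
Karamojong	11	1166	3716376	24.9	0.032	0.004	0.45	16	7	1092.82	766.55	1
Nganda10	10	1950	6070609	44.8	0.067	0.069	0.50	31	14	2138.62	2837.64	5
Nganda17	17	2232	6570952	51.1	0.051	0.028	0.50	18	7	969.06	357.18	2
Nkedi	19	2440	7542463	56.7	0.051	0.058	0.55	11	8	943.23	1069.77	3
Ntuku	19	2964	7338371	62.2	0.062	0.024	0.45	20	10	837.21	268.75	3
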