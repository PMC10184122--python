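# Published per-complex total rupture PMF (sum over the three interface
# H-bonds, kcal/mol) as printed; three columns disagree with the re-added
# per-bond values at one decimal (see energetics.build_energetics_table).
complex	sum_pmf_kcal_mol	sd_kcal_mol
wt_LEN	28.0	0.7
wt_noLEN	12.4	1.1
I35G	24.5	0.7
I37E	22.7	0.8
N39G	16.9	1.1
G40N	12.4	2.4
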