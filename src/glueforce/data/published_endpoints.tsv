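# Published per-bond H-bond rupture PMF endpoints (kcal/mol) for the six
# CRBN-CK1a complexes: wild-type ternary (wt_LEN), wild-type binary without
# lenalidomide (wt_noLEN), and four CK1a point mutants in the ternary complex.
# Errors are bootstrap sd over 10 resamples of the work profiles.
complex	bond	pmf_kcal_mol	sd_kcal_mol
wt_LEN	W400-N39	10.9	0.3
wt_LEN	H357-T38	6.2	0.3
wt_LEN	N351-I37	10.9	0.1
wt_noLEN	W400-N39	2.3	0.3
wt_noLEN	H357-T38	3.7	0.6
wt_noLEN	N351-I37	6.5	0.2
I35G	W400-N39	10.3	0.3
I35G	H357-T38	5.8	0.2
I35G	N351-I37	8.4	0.2
I37E	W400-N39	10.7	0.3
I37E	H357-T38	5.2	0.2
I37E	N351-I37	6.8	0.3
N39G	W400-N39	6.3	0.4
N39G	H357-T38	4.5	0.1
N39G	N351-I37	6.2	0.6
G40N	W400-N39	-0.4	1.2
G40N	H357-T38	6.2	0.3
G40N	N351-I37	5.8	1.0
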