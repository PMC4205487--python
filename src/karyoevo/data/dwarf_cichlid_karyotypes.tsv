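species	2n	karyotype	cma3_signals
Cleithracara maronii	50	14sm+36st-a	1 sm pair
Ivanacara adoketa	48	16m-sm+32st-a	1 st-a pair
Nannacara anomala	44	18m-sm+26st-a	1 m-sm pair
Nannacara aureocephalus	44	18m-sm+26st-a	3 m-sm pair
Nannacara taenia	44	16m-sm+28st-a	1 st-a pair
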