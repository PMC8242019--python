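rsid	chrom	pos	effect_allele	ref_allele	beta_iAs	se_iAs	beta_MMA	se_MMA	beta_DMA	se_DMA
rs9527	10	104623578	T	C	1.81	0.37	2.01	0.28	-3.82	0.48
rs11191527	10	104795134	C	T	1.32	0.27	0.98	0.20	-2.30	0.35
rs61735836	21	47572887	A	G	2.71	0.37	2.42	0.29	-5.09	0.51
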