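# subset_label=TGM
src_name	src_type	src_slice	dst_name	dst_type	dst_slice	weight	bootstrap_score
Eubacterium siraeum	taxon	1	uridine kinase	gene	1	0.31	0.8
uridine kinase	gene	1	cytidine	metabolite	1	0.55	0.7
cytidine	metabolite	0	Bacteroides thetaiotaomicron	taxon	1	0.6	0.9
uridine	metabolite	0	Bacteroides thetaiotaomicron	taxon	1	0.2	0.5
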