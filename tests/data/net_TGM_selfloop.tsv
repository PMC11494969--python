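# subset_label=TGM
src_name	src_type	src_slice	dst_name	dst_type	dst_slice	weight	bootstrap_score
Bacteroides stercoris	taxon	1	uridine kinase	gene	1	0.4	0.85
uridine kinase	gene	1	cytidine	metabolite	1	0.5	0.8
cytidine	metabolite	0	Bacteroides stercoris	taxon	1	0.45	0.75
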