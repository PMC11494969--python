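# subset_label=T
src_name	src_type	src_slice	dst_name	dst_type	dst_slice	weight	bootstrap_score
Eubacterium siraeum	taxon	0	Bacteroides thetaiotaomicron	taxon	1	0.42	0.9
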