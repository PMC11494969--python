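# subset_label=T
src_name	src_type	src_slice	dst_name	dst_type	dst_slice	weight	bootstrap_score
Bacteroides stercoris	taxon	0	Bacteroides stercoris	taxon	1	0.7	0.95
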