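# subset_label=G
src_name	src_type	src_slice	dst_name	dst_type	dst_slice	weight	bootstrap_score
thymidylate synthase	gene	0	glutamate dehydrogenase	gene	1	0.33	0.8
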