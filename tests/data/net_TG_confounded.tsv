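# subset_label=TG
src_name	src_type	src_slice	dst_name	dst_type	dst_slice	weight	bootstrap_score
Haemophilus parainfluenzae	taxon	1	thymidylate synthase	gene	1	0.5	0.9
Haemophilus parainfluenzae	taxon	1	glutamate dehydrogenase	gene	1	0.4	0.7
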