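patient_id	sample_type	brca_context	gene	consequence	hgvs_p	vaf	present_pre_parpi	category
65879	post_parpi	BRCA1	ARID1A	stop_gained	p.Gln878Ter	0.05	NA	potential
15266	post_parpi	BRCA2	CHEK2	missense_variant	p.Arg160Gly	0.44	NA	potential
15266	post_parpi	BRCA2	XRCC3	missense_variant	p.Thr241Met	0.48	NA	potential
15257	post_parpi	BRCA1	SHLD2	missense_variant	p.Trp11Arg	0.05	NA	potential
15276	post_parpi	BRCA1	SHLD2	stop_gained	p.Gln169Ter	0.37	no	potential
15284	post_parpi	BRCA1	SHLD2	missense_variant	p.Lys438Glu	0.16	NA	potential
15230	post_parpi	BRCA1	TP53BP1	missense_variant	p.Lys1141Gln	0.46	NA	potential
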