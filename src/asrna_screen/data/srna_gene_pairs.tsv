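# Published in-silico survey of sRNA genes antisense/adjacent to mRNAs up-regulated
# in the S. coelicolor rnc (RNase III deletion) mutant. One row per gene-sRNA pair;
# a gene may recur with several partner sRNAs. Arrow notation: -> / <- gene strand,
# => / <= sRNA strand, * unknown (ambiguous) sRNA strand.
gene_id	srna_id	source	category	arrows	comment
SCO0499	scr0500	moody2013	Ambiguous	-> * <-	mRNA up-regulated in rnc mutant
SCO0500	scr0500	moody2013	Ambiguous	-> * <-	mRNA up-regulated in rnc mutant
SCO1150	scr1150	moody2013	cutoRNA	-> <= <-	mRNA up-regulated in rnc mutant
SCO1565	scr1566	swiercz2008	Ambiguous	<- * ->	Predicted
SCO1626	scr1625	moody2013	cutoRNA	-> <= <-	as1625 analyzed
SCO1630	scr1631	swiercz2008	Ambiguous	<- * <-	Predicted
SCO1659	scr1659	swiercz2008	Ambiguous	-> * ->	Predicted
SCO1700	scr1700	dalia2010	cis_asRNA	<- => <-	Predicted by RNAz
SCO1906	scr1907	swiercz2008	Ambiguous	<- * <-	Predicted
SCO2197	scr2198	swiercz2008	Ambiguous	<- * ->	Predicted
SCO2198	scr2198	dalia2010	cis_asRNA	<- <= ->	Confirmed, as2198 analyzed
SCO3003	scr3004	swiercz2008	Ambiguous	<- * ->	Predicted
SCO3113	scr3114	swiercz2008	Ambiguous	-> * <-	Predicted
SCO3132	scr3133	dalia2010	cis_asRNA	-> <= <-	Predicted by RNAz
SCO3216	scr3216	swiercz2008	Ambiguous	<- * ->	Predicted
SCO3217	scr3217	swiercz2008	Ambiguous	-> * ->	Predicted
SCO4095	scr4096	swiercz2008	Ambiguous	-> * ->	Predicted
SCO4142	scr4143	swiercz2008	Ambiguous	<- * <-	Predicted
SCO4144	scr4145	swiercz2008	Ambiguous	<- * <-	Predicted
SCO4145	scr4145	swiercz2008	Ambiguous	<- * <-	Predicted
SCO4145	scr4146	swiercz2008	Ambiguous	<- * ->	Predicted
SCO4229	scr4229	swiercz2008	Ambiguous	<- * ->	Predicted
SCO4249	scr4249	swiercz2008	Ambiguous	<- * ->	Predicted
SCO4283	scr4283	moody2013	cutoRNA	-> <= <-	mRNA up-regulated in rnc mutant
SCO4698	scr4699	moody2013	Ambiguous	-> <= ->	Predicted
SCO4748	scr4749	moody2013	cutoRNA	-> => <-	mRNA up-regulated in rnc mutant
SCO4882	scr4883	swiercz2008	Ambiguous	-> * ->	Predicted
SCO4947	scr4947	swiercz2008	Ambiguous	-> * ->	Predicted
SCO5106	scr5106	moody2013	cutoRNA	-> => <-	mRNA up-regulated in rnc mutant
SCO5112	scr5112	swiercz2008	cis_asRNA	-> * ->	Predicted, as5112 analyzed
SCO5142	scr5143	moody2013	Ambiguous	-> <= ->	Predicted
SCO5145	scr5145	swiercz2008	Ambiguous	<- * ->	Predicted
SCO5145	scr5146	moody2013	cutoRNA	-> => <-	mRNA up-regulated in rnc mutant
SCO5163	scr5164	swiercz2008	Ambiguous	<- * ->	Predicted
SCO5476	scr5476	swiercz2008	Ambiguous	-> * ->	Predicted
SCO5519	scr5518	moody2013	Ambiguous	<- * ->	Predicted
SCO5520	scr5521	swiercz2008	Ambiguous	-> * ->	Predicted
SCO5521	scr5521	swiercz2008	Ambiguous	-> * ->	Predicted
SCO5536	scr5536	panek2008	Ambiguous	<- * ->	Termed #234
SCO5537	scr5537	swiercz2008	Ambiguous	-> * <-	Predicted
SCO5757	scr5756	swiercz2008	Ambiguous	-> * ->	Predicted
SCO6277	scr6277	moody2013	cis_asRNA	-> <= ->	mRNA up-regulated in rnc mutant
SCO6283	scr6284	moody2013	Ambiguous	-> * ->	Predicted
SCO6284	scr6284	moody2013	Ambiguous	-> * ->	Predicted
SCO6284	scr6285	moody2013	Ambiguous	-> <= ->	Predicted
SCO6396	scr6396	moody2013	Ambiguous	-> * ->	Predicted
SCO6716	scr6716	moody2013	cutoRNA	-> <= <-	mRNA up-regulated in rnc mutant
SCO6716	scr6717	moody2013	cutoRNA	-> => <-	-
SCO6728	scr6729	moody2013	cutoRNA	-> => <-	mRNA up-regulated in rnc mutant
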