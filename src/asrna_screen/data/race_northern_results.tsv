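# Published RACE / northern outcomes for the 30 genes tested for antisense
# expression in S. coelicolor. The experimental set are mRNAs co-precipitated with
# RNase III in vivo (BARD enrichment ratio and fold increase in the rnc mutant
# given); the control set are in-vitro RNase III substrates and sigma-factor genes.
# five_prime / three_prime: RACE end detection; northern: blot signal detected.
gene_id	set	product	relation	bard_ratio	fold_change	five_prime	three_prime	northern
SCO0168	experimental	Possible regulatory protein	coprecipitated	100	2.41	+	-	-
SCO0198	experimental	Hypothetical protein	coprecipitated	47.6	2.70	+	+	+
SCO0219	experimental	Putative nitrate reductase delta chain	coprecipitated	30	2.18	+	+	+
SCO0323	experimental	Hypothetical protein	coprecipitated	138	1.62	+	+	+
SCO0494	experimental	Probable iron-siderophore binding lipoprotein	coprecipitated	19	-2.14	+	+	+
SCO0703	experimental	Putative regulatory protein	coprecipitated	119	1.36	+	+	+
SCO0772	experimental	Putative regulatory protein	coprecipitated	3	2.46	+	+	+
SCO0864	experimental	Probable ECF-family sigma factor	coprecipitated	234	1.70	+	+	+
SCO1626	experimental	Cytochrome P450	coprecipitated	22.8	-2.6	+	+	+
SCO2081	experimental	Hypothetical protein	coprecipitated	86	1.23	+	+	-
SCO2198	experimental	Glutamine synthetase I	coprecipitated	12.4	2.9	+	+	+
SCO3983	experimental	Hypothetical protein	coprecipitated	1.5	2.14	+	+	+
SCO4077	experimental	Hypothetical protein	coprecipitated	184	-1.01	+	+	+
SCO4878	experimental	Glycosyltransferase	coprecipitated	1.6	2.00	+	+	-
SCO5040	experimental	Hypothetical protein	coprecipitated	122	1.22	+	+	-
SCO5112	experimental	Putative ABC transport system integral membrane protein BldKA	coprecipitated	1.4	2.56	+	+	+
SCO5123	experimental	Small membrane protein	coprecipitated	247	1.24	+	+	+
SCO2792	control	AdpA	in_vitro_binding			+	+	+
SCO5572	control	RNase III	in_vitro_binding			+	+	+
SCO5737	control	Guanosine pentaphosphate synthetase/polyribonucleotide nucleotidyltransferase	in_vitro_binding			-	-	-
SCO0600	control	RNA polymerase sigma factor SigB	unknown			+	+	+
SCO0895	control	RNA polymerase sigma factor HrdC	unknown			-	-	-
SCO2465	control	RNA polymerase sigma factor HrdA	unknown			-	-	-
SCO3202	control	RNA polymerase sigma factor HrdD	unknown			-	-	-
SCO3356	control	RNA polymerase sigma factor SigE	unknown			-	-	-
SCO4769	control	RNA polymerase sigma factor SigD	unknown			-	-	-
SCO5216	control	RNA polymerase sigma factor SigR	unknown			+	+	+
SCO5243	control	RNA polymerase sigma factor SigH	unknown			+	+	+
SCO5621	control	RNA polymerase sigma factor WhiG	unknown			-	-	-
SCO5820	control	RNA polymerase sigma factor HrdB	unknown			-	-	-
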