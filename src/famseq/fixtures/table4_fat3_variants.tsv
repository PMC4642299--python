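# FAT3 variants (decimal commas preserved as printed; N = absent from the
# database; NA = not available).  Predictor codes: SIFT T/D, Polyphen-2 B/P/D,
# MutationTaster D/N, logistic-regression Y.
family	variant	public_db_maf	exac_maf	mgp_maf	sift	polyphen	mutation_taster	logistic_regression
2	c.8680G>T:p.Val2894Leu	0,000236742	3,00E-05	NA	T	B	D	Y
3	c.2873T>C:p.Leu958Pro	0,000681	0,000765	0,0019	D	D	D	Y
4	c.13193G>A:p.Gly4398Asp	0,002501191	0,001971	0,0037	D	D	D	Y
6	c.3472A>G:p.Met1158Val	N	1,50E-05	NA	T	P	N	Y
7	c.6916G>A:p.Val2306Ile	N	N	NA	T	D	D	Y
7	c.6932C>G:p.Ser2311Cys	N	N	NA	D	P	D	Y
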