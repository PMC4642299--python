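family_id	patient_id	gender	phenotype	prescreening	inheritance	rs2435357
1	III.3	Male	TCA	Negative	-	T/T
1	II.2	Male	NA	RET:c.2371T>A:p.Tyr791Asn	Maternal	T/C
2	II.4	Female	S-HSCR	Negative	-	T/C
2	II.5	Male	S-HSCR	Negative	-	T/C
3	III.1	Male	S-HSCR	NTF3:c.226G>A:p.Gly76Arg	Paternal	T/T
3	III.2	Male	L-HSCR	PHOX2B:c.741_761del;SEMA3D:c.185_186insT:p.Leu62fs	Maternal	C/C
4	II.2	Male	NA	PHOX2B:c.745_765del	Maternal	T/T
4	II.8	Female	S-HSCR	Negative	-	T/C
5	I.2	Female	NA	Negative	-	C/C
5	II.1	Female	L-HSCR	RET:c.844G>T:p.Val282Leu	Paternal	C/C
6	II.2	Male	NA	Negative	-	T/C
6	II.1	Male	NA	Negative	-	T/C
7	III.1	Male	S-HSCR	Negative	-	T/T
7	IV.1	Male	S-HSCR	SEMA3D:c.592G>A:p.Glu198Lys	Maternal	T/C
8	II.1	Male	NA	EDNRB:c.466C>T:p.Pro156Ser	Paternal	T/T
8	II.2	Male	NA	EDNRB:c.466C>T:p.Pro156Ser	Paternal	T/T
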