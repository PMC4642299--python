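# Recurrent-gene table as printed (decimal commas preserved; the loader
# normalizes them to points).  families_shared: families where both patients
# carry the same variant; families_single: family:patient pairs with a
# variant in only one patient.
gene	families_shared	families_single	n_variants	p_value	lod
FAT3	2, 3, 6	4:II.8;7:III.1;7:IV.1	6	0,0040	1,25
RHOBTB3	1, 5	0	2	0,0193	0,84
CNTN5	5, 8	0	2	0,1300	0,09
TSC2	2, 6	0	2	0,1360	0,30
FAT4	2, 5	3:III.1;6:II.1	4	0,1660	0,75
DNAH9	2, 8	6:II.2	4	0,1830	0,47
IGSF10	1, 2	3:III.2	3	0,2670	0,00
PLEC	2, 8	0	2	0,4260	0,84
TTN	5, 6	4:II.2	3	0,9410	0,23
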