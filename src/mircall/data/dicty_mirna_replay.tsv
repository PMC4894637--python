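# Worked example: known and newly identified D. discoideum miRNA loci.
# One row per sequenced arm; relative expression per strain (AX2 wild type,
# rbdB- processing mutant, agnA- suppressor mutant) as printed, with decimal
# commas.  hairpin/star/northern are per-locus flags; override_c2/override_c3
# mark criteria credited from Northern blot evidence; known marks loci
# attributed to prior publications.
locus_id	arm	sequence	wt	proc_mutant	supp_mutant	hairpin	star	northern	override_c2	override_c3	known
ddi-miR-1176	5p	CCAAUUUUUAUCAAGGAAAGC	16,00	3,30	1341,16	1	1	1	0	0	1
ddi-miR-1176	3p	CUUCCUUGACAAAAAUUGCCC	1,00	0,00	1,11	1	1	1	0	0	1
ddi-miR-1177	5p	CCAGUUAGGGUUUAAUGGUUC	3,00	0,00	36,52	1	1	1	0	0	1
ddi-miR-1177	3p	ACCGUUGAGCCCUUUCUGAUU	7,00	0,00	167,09	1	1	1	0	0	1
miRNA_can_D1	5p	UCUUUCUCUAAUUUCAUUUAUU	54,00	0,00	588,69	1	1	1	0	0	0
miRNA_can_D1	3p	AAAUGAAAUUAGAGAAAGGGAU	8,00	1,65	79,67	1	1	1	0	0	0
miRNA_can_D2	5p	UUCUCGACAGACAUAGCAUUGG	14,00	1,65	915,13	1	1	1	0	0	0
miRNA_can_D2	3p	AAUGCUUAGAUGUAGAGGAAAC	0,00	0,82	9,96	1	1	1	0	0	0
ddi-mir-7097	5p	UCUCUACUAGUGCCGAAAUCA	66,00	12,36	2599,33	1	1	1	0	0	1
ddi-mir-7097	3p	UUUGGCAGAAGUAGAGACGAA	10,00	5,77	590,91	1	1	1	0	0	1
miRNA_can_D3	3p	AUUAAUUUCGGCAGCCAUAUU	68,00	3,30	185,90	1	1	1	0	0	0
miRNA_can_D3	5p	UAUGGCUGCUGAAAUUAAUGUGG	47,00	26,37	369,59	1	1	1	0	0	0
miRNA-like_D4	5p	UCGAACUAGUCCAAUCUUUAAU	12,00	754,68	24,72	0	0	1	1	1	0
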