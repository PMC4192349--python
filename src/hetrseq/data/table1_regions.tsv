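# HetR ChIP-seq peak regions (curated-region table).
# Coordinates are 1-based with an exclusive end, so length_bp = end - start.
# footnote codes: '-' none (region within 500 bp upstream of the ORF),
#   b not applicable, c downstream of a potential TSS, d >500 bp upstream.
# fc columns: signed RPKM fold change in the hetR-null mutant at 6 h;
#   sentinels NA, "Low coverage", and "n / 0".
# end_reliable 'n' marks the one row whose printed end coordinate is
#   inconsistent with its printed length; it is excluded from length checks.
region_id	start	end	length_bp	gene_left	footnote_left	fc_left	gene_right	footnote_right	fc_right	binding_site	end_reliable
R01	136127	136558	431	all0131	-	Low coverage	alr0132	-	-1.1	Yes	y
R02	613436	613919	483	patA (all0521)	-	-8.0	alr0522	d	-5.6	Yes	y
R03	1729122	1729569	447	all1467	-	1.4	alr1468	-	Low coverage	Yes	y
R04	1732738	1733693	955	asr1469	c	1.7	alr1470	-	-3.1	Yes	y
R05	1734763	1735224	461	all1471	-	-2.3	all1472	c	-1.6	Yes	y
R06	1788499	1788932	433	alr1527	-	-5.8	alr1528	d	NA	Yes	y
R07	2427714	2428147	433	all2027	-	3.8	asl2028	-	-1.5	Yes	y
R08	2691579	2692024	445	all2239	-	-4.0	alr2240	-	-7.1	Yes	y
R09	2820376	2822006	678	alr2338	c	-4.4	hetR (alr2339)	-	-131	Yes	n
R10	3431297	3432038	741	hetC (alr2817)	c	NA	hetP (alr2818)	-	-4.4	Yes	y
R11	3627499	3627977	478	alr2986	c	-3.0	alr2987	d	NA	Yes	y
R12	3695599	3696450	851	asr3053	c	2.1	all3054	d	NA	Yes	y
R13	3821175	3821606	431	alr3156	c	NA	aphA (alr3157)	-	-7.7	Yes	y
R14	4383426	4383866	440	avaIR (all3631)	d	-1.3	avaIM (all3632)	c	-1.9	Yes	y
R15	4539927	4540364	437	alr3757	c	NA	alr3758	-	11 / 0	Yes	y
R16	4740704	4741151	447	alr3926	c	NA	all3927	c	-2.9	Yes	y
R17	5064797	5065242	445	asr4228	c	NA	alr4229	-	-7.5	Yes	y
R18	5303024	5303480	456	all4424	-	5.2	all4425	c	1.7	Yes	y
R19	5309952	5310383	431	all4430	-	4.9	all4431	c	10.3	Yes	y
R20	5355615	5356047	432	alr4469	c	-1.3	asr4470	-	-10.8	Yes	y
R21	374646	375090	444	all0326	-	Low coverage	all0327	c	NA	No	y
R22	2274728	2275590	862	alr1903	c	-4.9	cyaB2 (all1904)	c	NA	No	y
R23	2693489	2693944	455	alr2241	c	NA	alr2242	-	-13.4	No	y
R24	2706756	2707187	431	gvpA (asl2254)	-	-6.3	asr2255	-	Low coverage	No	y
R25	4857231	4857672	441	alr4031	c	NA	alr4032	-	Low coverage	No	y
R26	6129044	6129475	431	all5131	-	-4.2	all5132	c	-2.5	No	y
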