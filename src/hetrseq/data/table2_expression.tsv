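# Candidate HetR targets chosen for follow-up, with RNA-seq RPKM fold changes.
# fc_wt0_vs_hetr0 / fc_wt6_vs_hetr6: signed fold, WT over hetR-null mutant at
#   0 h and 6 h after nitrogen step-down (negative = lower in the mutant).
# fc_wt0_vs_wt6/12/21: WT time-course folds relative to 0 h.
# Sentinels: NA, "Low coverage", and "n / 0" (n WT reads dropped to 0 in the mutant).
gene_id	locus	fc_wt0_vs_hetr0	fc_wt6_vs_hetr6	fc_wt0_vs_wt6	fc_wt0_vs_wt12	fc_wt0_vs_wt21	function	binding_site
patA	all0521	-13	-8.0	-1.8	1.6	1.4	Pattern formation	TTGGCTCAAACCCAT
asr1469	asr1469	-4.0	1.7	NA	Low coverage	NA	Small peptide	TTGGGTCTAACTTAT
asl2028	asl2028	-2.5	-1.5	-3.7	1.2	1.4	Unknown	TCGGGGTAACAATCC
alr2242	alr2242	1.3	-13.4	1.5	1.1	2.7	Possible NTPase	None found
alr3758	alr3758	Low coverage	11 / 0	12	3.9	7.7	Anti sigma factor antagonist	TTGGGTAAACCTGCT
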