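gene	chrom	start	end
APC	5	112043195	112181936
TP53	17	7571720	7590868
KRAS	12	25358180	25403854
PIK3CA	3	178866311	178952497
BRAF	7	140419127	140624564
EGFR	7	55086714	55324313
ERBB2	17	37844393	37884915
ERBB3	12	56473891	56497289
FGFR1	8	38268656	38326352
NRAS	1	115247085	115259515
HRAS	11	532242	535550
IRS1	2	227596033	227664475
MAP2K1	15	66679155	66784650
MET	7	116312444	116438440
PDGFRB	5	149493400	149535435
PTEN	10	89623195	89728532
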