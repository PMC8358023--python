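gene	aa_change	label
KRAS	p.Gly12Asp	KRAS G12D
KRAS	p.Gly12Val	KRAS G12V
KRAS	p.Gly12Cys	KRAS G12C
KRAS	p.Gly12Ser	KRAS G12S
KRAS	p.Gly12Ala	KRAS G12A
KRAS	p.Gly12Arg	KRAS G12R
KRAS	p.Gly13Asp	KRAS G13D
KRAS	p.Gly13Cys	KRAS G13C
KRAS	p.Gln61His	KRAS Q61H
KRAS	p.Gln61Arg	KRAS Q61R
KRAS	p.Gln61Leu	KRAS Q61L
KRAS	p.Gln61Lys	KRAS Q61K
NRAS	p.Gly12Asp	NRAS G12D
NRAS	p.Gly12Val	NRAS G12V
NRAS	p.Gly12Cys	NRAS G12C
NRAS	p.Gly13Asp	NRAS G13D
NRAS	p.Gly13Arg	NRAS G13R
NRAS	p.Gly13Val	NRAS G13V
NRAS	p.Gln61Arg	NRAS Q61R
NRAS	p.Gln61Lys	NRAS Q61K
NRAS	p.Gln61Leu	NRAS Q61L
NRAS	p.Gln61His	NRAS Q61H
BRAF	p.Val600Glu	BRAF V600E
MAP2K1	p.Lys57Thr	MAP2K1 K57T
MAP2K1	p.Lys57Asn	MAP2K1 K57N
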