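gene	base_change	classification
KRAS	c.35G>T	pathogenic
KRAS	c.35G>A	pathogenic
KRAS	c.34G>T	pathogenic
KRAS	c.38G>A	pathogenic
KRAS	c.183A>C	pathogenic
NRAS	c.182A>G	pathogenic
BRAF	c.1799T>A	pathogenic
MAP2K1	c.171G>T	pathogenic
MAP2K1	c.170A>C	likely_pathogenic
TP53	c.733G>A	pathogenic
APC	c.4348C>T	pathogenic
APC	c.6610C>T	likely_pathogenic
PTEN	c.518G>A	pathogenic
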