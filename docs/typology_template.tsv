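# Typology template for the noun-phrase order analysis.
# order: a permutation of the slot labels D (determiner), N (numeral),
#        A (adjective), n (noun), head-initial reading left to right.
# count: number of unrelated language genera attesting the order.
# Fill in counts from a typological survey; rows with count 0 are
# excluded from the log-count regression.
order	count
DNAn	0
DNnA	0
DANn	0
DAnN	0
DnNA	0
DnAN	0
NDAn	0
NDnA	0
NADn	0
NAnD	0
NnDA	0
NnAD	0
ADNn	0
ADnN	0
ANDn	0
ANnD	0
AnDN	0
AnND	0
nDNA	0
nDAN	0
nNDA	0
nNAD	0
nADN	0
nAND	0
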