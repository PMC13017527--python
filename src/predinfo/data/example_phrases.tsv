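# Example noun-phrase count table (determiner / numeral / adjective / noun slots).
# Empty field = slot absent. Tab-delimited, UTF-8.
determiner	numeral	adjective	noun	count
die			Hand	234
ein		alt	Kind	4
	drei		Buch	2
ein		einzigartig	Parfümeur	1
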