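type	pos	reference	Ls-S2-53	Ls-S2-76
Syn	29162859	A	G	G
Syn	29162874	C	T	T
FRAME_SHIFT	29162967	CAC	CAC, A	A
Syn	29163022	G	G, T	T
Nonsyn	29163188	T	C	C
Syn	29163231	T	C	C
Nonsyn	29163281	A	G	G
Nonsyn	29163300	G	T	T
Syn	29163420	C	T	T
Syn	29163461	A	A, C	C
Nonsyn	29163566	A	C	C
Syn	29163618	G	A	A
Syn	29163639	C	T	T
Nonsyn	29163668	T	T, C	T
FRAME_SHIFT	29163671	ACTGTAAATTTGTCAAGTCAAATATCCGGGGA	AATGTAAATTTGTCAAGTCAAATATCCGGGGA, A	AATGTAAATTTGTCAAGTCAAATATCCGGGGA
Syn	29163735	G	G, A	G
Syn	29163764	G	A	A
Syn	29163836	C	T	T
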