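position	ref	alt	label
3243	A	G	MELAS/MIDD
11778	G	A	LHON
13513	G	A	Leigh
14484	T	C	LHON
3460	G	A	LHON
8344	A	G	MERRF
8993	T	G	NARP/Leigh
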