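# aminoacyl-tRNA synthetase class/subclass per amino acid
# class: I, II, or BOTH (Lys only; LysRS has class I and class II forms)
# subclass: a, b, or c
Ala	II	a
Arg	I	a
Asn	II	b
Asp	II	b
Cys	I	a
Gln	I	b
Glu	I	b
Gly	II	a
His	II	a
Ile	I	a
Leu	I	a
Lys	BOTH	b
Met	I	a
Phe	II	c
Pro	II	a
Ser	II	a
Thr	II	a
Trp	I	c
Tyr	I	c
Val	I	a
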