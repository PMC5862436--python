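variant	canonical
ɛ	e
œ	ø
ɔ	o
ɑ	a
ʌ	ə
ɜ	ə
ɪ	i
ʊ	u
ʏ	y
ɡ	g
q	k
ʀ	ʁ
ɾ	r
ɹ	r
ʎ	j
ç	ʃ
ʋ	v
β	v
ð	z
θ	s
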