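symbol	sonorant	syllabic	consonantal	continuant	nasal	high	low	back	round	anterior	coronal	voiced	place	manner
p	0	0	1	0	0	0	0	0	0	1	0	0	labial	plosive
b	0	0	1	0	0	0	0	0	0	1	0	1	labial	plosive
t	0	0	1	0	0	0	0	0	0	1	1	0	coronal	plosive
d	0	0	1	0	0	0	0	0	0	1	1	1	coronal	plosive
k	0	0	1	0	0	1	0	1	0	0	0	0	dorsal	plosive
g	0	0	1	0	0	1	0	1	0	0	0	1	dorsal	plosive
ʔ	0	0	1	0	0	0	0	0	0	0	0	0	radical	plosive
m	1	0	1	0	1	0	0	0	0	1	0	1	labial	nasal
n	1	0	1	0	1	0	0	0	0	1	1	1	coronal	nasal
ɲ	1	0	1	0	1	1	0	0	0	0	0	1	dorsal	nasal
ŋ	1	0	1	0	1	1	0	1	0	0	0	1	dorsal	nasal
f	0	0	1	1	0	0	0	0	0	1	0	0	labial	fricative
v	0	0	1	1	0	0	0	0	0	1	0	1	labial	fricative
s	0	0	1	1	0	0	0	0	0	1	1	0	coronal	fricative
z	0	0	1	1	0	0	0	0	0	1	1	1	coronal	fricative
ʃ	0	0	1	1	0	1	0	0	0	0	1	0	coronal	fricative
ʒ	0	0	1	1	0	1	0	0	0	0	1	1	coronal	fricative
x	0	0	1	1	0	1	0	1	0	0	0	0	dorsal	fricative
h	0	0	1	1	0	0	0	0	0	0	0	0	radical	fricative
l	1	0	1	0	0	0	0	0	0	1	1	1	coronal	liquid
r	1	0	1	1	0	0	0	0	0	1	1	1	coronal	liquid
ʁ	1	0	1	1	0	0	0	1	0	0	0	1	dorsal	liquid
j	1	0	1	1	0	1	0	0	0	0	0	1	dorsal	liquid
w	1	0	1	1	0	1	0	1	1	0	0	1	dorsal	liquid
i	1	1	0	1	0	1	0	0	0	0	0	1
y	1	1	0	1	0	1	0	0	1	0	0	1
u	1	1	0	1	0	1	0	1	1	0	0	1
e	1	1	0	1	0	0	0	0	0	0	0	1
ø	1	1	0	1	0	0	0	0	1	0	0	1
o	1	1	0	1	0	0	0	1	1	0	0	1
ə	1	1	0	1	0	0	0	1	0	0	0	1
a	1	1	0	1	0	0	1	0	0	0	0	1
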