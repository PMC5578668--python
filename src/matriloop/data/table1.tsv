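family	n_studied	n_available	haplotype	haplogroup
El Dahma	23	19	M1	D3
Bint El Bahreyn	9	8	M2	I
Roga El Beida	4	4	M3	D3
Ghazieh I	13	8	M4	X3c1
Jellabiet Feysul	7	6	M4	X3c1
Venus	12	11	M5	K3
Rodania	11	9	M5	K3
Bint Karima	2	2	M5	K3
Hind	7	7	M5	K3
El Obeya Om Grees	7	5	M6	A
El Kahila	11	10	M7	X3
Mabrouka	8	8	M8	F
Nafaa	5	3	M9	No designation
El Samraa	7	7	M10	X2
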