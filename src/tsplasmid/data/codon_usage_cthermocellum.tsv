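codon	aa	fraction
TTT	F	0.72
TTC	F	0.28
TTA	L	0.28
TTG	L	0.12
CTT	L	0.24
CTC	L	0.06
CTA	L	0.10
CTG	L	0.20
ATT	I	0.48
ATC	I	0.22
ATA	I	0.30
ATG	M	1.00
GTT	V	0.36
GTC	V	0.10
GTA	V	0.28
GTG	V	0.26
TCT	S	0.20
TCC	S	0.08
TCA	S	0.20
TCG	S	0.06
AGT	S	0.26
AGC	S	0.20
CCT	P	0.32
CCC	P	0.08
CCA	P	0.38
CCG	P	0.22
ACT	T	0.26
ACC	T	0.14
ACA	T	0.40
ACG	T	0.20
GCT	A	0.30
GCC	A	0.14
GCA	A	0.36
GCG	A	0.20
TAT	Y	0.68
TAC	Y	0.32
CAT	H	0.66
CAC	H	0.34
CAA	Q	0.62
CAG	Q	0.38
AAT	N	0.62
AAC	N	0.38
AAA	K	0.66
AAG	K	0.34
GAT	D	0.66
GAC	D	0.34
GAA	E	0.70
GAG	E	0.30
TGT	C	0.58
TGC	C	0.42
TGG	W	1.00
CGT	R	0.14
CGC	R	0.06
CGA	R	0.10
CGG	R	0.06
AGA	R	0.44
AGG	R	0.20
GGT	G	0.24
GGC	G	0.14
GGA	G	0.42
GGG	G	0.20
TAA	*	0.60
TAG	*	0.16
TGA	*	0.24
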