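# Default optimal-codon set: a chicken-like, GC-ending preferred codon per
# degenerate amino acid. This is a bundled default for exploration and
# testing; supply a species-specific table for real analyses.
# amino_acid	codon
A	GCC
C	TGC
D	GAC
E	GAG
F	TTC
G	GGC
H	CAC
I	ATC
K	AAG
L	CTG
N	AAC
P	CCC
Q	CAG
R	CGC
S	AGC
T	ACC
V	GTG
Y	TAC
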