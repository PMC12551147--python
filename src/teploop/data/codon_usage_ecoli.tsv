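# Genome-wide codon usage for Escherichia coli K-12 (per 1000 codons), transcribed
# from the standard Kazusa-style codon usage tabulation of the K-12 genome.
# Relative adaptiveness weights for reverse translation are derived at load time as
# w(codon) = freq(codon) / max freq among synonymous codons of the same amino acid.
# Stop codons carry amino_acid "*" and are never used for reverse translation.
codon	amino_acid	per_thousand
TTT	F	22.2
TTC	F	16.6
TTA	L	13.9
TTG	L	13.7
CTT	L	11.0
CTC	L	11.0
CTA	L	3.9
CTG	L	52.6
ATT	I	30.3
ATC	I	25.1
ATA	I	4.4
ATG	M	27.9
GTT	V	18.3
GTC	V	15.3
GTA	V	10.9
GTG	V	26.4
TCT	S	8.5
TCC	S	8.6
TCA	S	7.2
TCG	S	8.9
CCT	P	7.0
CCC	P	5.5
CCA	P	8.4
CCG	P	23.2
ACT	T	9.0
ACC	T	23.4
ACA	T	7.1
ACG	T	14.4
GCT	A	15.3
GCC	A	25.5
GCA	A	20.3
GCG	A	33.6
TAT	Y	16.2
TAC	Y	12.2
TAA	*	2.0
TAG	*	0.2
CAT	H	12.9
CAC	H	9.7
CAA	Q	15.3
CAG	Q	28.8
AAT	N	17.7
AAC	N	21.7
AAA	K	33.6
AAG	K	10.3
GAT	D	32.1
GAC	D	19.1
GAA	E	39.4
GAG	E	17.8
TGT	C	5.2
TGC	C	6.4
TGA	*	0.9
TGG	W	15.2
CGT	R	20.9
CGC	R	22.0
CGA	R	3.6
CGG	R	5.4
AGT	S	8.8
AGC	S	16.1
AGA	R	2.1
AGG	R	1.2
GGT	G	24.7
GGC	G	29.6
GGA	G	8.0
GGG	G	11.1
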