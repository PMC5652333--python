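# free_amino_acid_v1: atom counts of the free (unpolymerised) standard amino acids
residue	C	H	N	O	S
A	3	7	1	2	0
C	3	7	1	2	1
D	4	7	1	4	0
E	5	9	1	4	0
F	9	11	1	2	0
G	2	5	1	2	0
H	6	9	3	2	0
I	6	13	1	2	0
K	6	14	2	2	0
L	6	13	1	2	0
M	5	11	1	2	1
N	4	8	2	3	0
P	5	9	1	2	0
Q	5	10	2	3	0
R	6	14	4	2	0
S	3	7	1	3	0
T	4	9	1	3	0
V	5	11	1	2	0
W	11	12	2	2	0
Y	9	11	1	3	0
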