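# BLOSUM62 with query-side background frequencies replaced by NNK-library
# amino-acid frequencies (f_i = NNK codons for i / 32; N=ACGT, K=G/T).
# Rows: query (library peptide) residue; columns: antigen residue.
# Half-bit scale, rounded to integers. Regenerate with
# mimomap.align.derive_nnk_matrix().
   A  C  D  E  F  G  H  I  K  L  M  N  P  Q  R  S  T  V  W  Y
A  4  0 -2 -1 -2  0 -2 -1 -1 -1 -1 -2 -1 -1 -1  1  0  0 -3 -2
C -1  8 -4 -5 -3 -4 -4 -2 -4 -2 -2 -4 -4 -4 -4 -2 -2 -2 -3 -3
D  0 -1  8  4 -1  1  1 -1  1 -2 -1  3  1  2  0  2  1 -1 -2 -1
E  1 -2  4  7 -1  0  2 -1  3 -1  0  2  1  4  2  2  1  0 -1  0
F -1 -1 -2 -2  7 -2  0  1 -2  1  1 -2 -3 -2 -2 -1 -1  0  2  4
G  0 -3 -1 -2 -3  6 -2 -4 -2 -4 -3  0 -2 -2 -2  0 -2 -3 -2 -3
H -3 -4 -2 -1 -2 -3  7 -4 -2 -4 -3  0 -3 -1 -1 -2 -3 -4 -3  1
I  1  1 -1 -1  2 -2 -1  6 -1  4  3 -1 -1 -1 -1  0  1  5 -1  1
K  1 -1  1  3 -1  0  1 -1  7  0  1  2  1  3  4  2  1  0 -1  0
L -1 -1 -4 -3  0 -4 -3  2 -2  4  2 -3 -3 -2 -2 -2 -1  1 -2 -1
M -2 -2 -4 -3 -1 -4 -3  0 -2  1  4 -3 -3 -1 -2 -2 -2  0 -2 -2
N -1 -2  2  1 -2  1  2 -2  1 -2 -1  7 -1  1  1  2  1 -2 -3 -1
P -2 -4 -2 -2 -5 -3 -3 -4 -2 -4 -3 -3  6 -2 -3 -2 -2 -3 -5 -4
Q -1 -3  0  2 -3 -2  0 -3  1 -2  0  0 -1  5  1  0 -1 -2 -2 -1
R -3 -5 -4 -2 -5 -4 -2 -5  0 -4 -3 -2 -4 -1  3 -3 -3 -5 -5 -4
S  0 -2 -1 -1 -3 -1 -2 -3 -1 -3 -2  0 -2 -1 -2  3  0 -3 -4 -3
T -1 -2 -2 -2 -3 -3 -3 -2 -2 -2 -2 -1 -2 -2 -2  0  4 -1 -3 -3
V  0 -1 -3 -2 -1 -3 -3  3 -2  1  1 -3 -2 -2 -3 -2  0  4 -3 -1
W -6 -5 -7 -6 -2 -5 -5 -6 -6 -5 -4 -7 -7 -5 -6 -6 -5 -6  8 -1
Y -2 -2 -3 -2  3 -3  2 -1 -2 -1 -1 -2 -3 -1 -2 -2 -2 -1  2  7
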