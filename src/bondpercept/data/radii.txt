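# Single-bond covalent radii in Angstrom (Cordero et al. 2008).
# Used in the distance criterion: bond iff 0.8 < d_ij < r_i + r_j + 0.4.
# Editable: one "ELEMENT radius" pair per line; '#' starts a comment.
H  0.31
B  0.84
C  0.76
N  0.71
O  0.66
F  0.57
NA 1.66
MG 1.41
SI 1.11
P  1.07
S  1.05
CL 1.02
K  2.03
CA 1.76
FE 1.32
ZN 1.22
SE 1.20
BR 1.20
I  1.39
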