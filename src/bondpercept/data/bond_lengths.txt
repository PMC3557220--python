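# Reference bond lengths (Angstrom) for the length rules.
# Columns: element pair, L1 (single-bond threshold), L2 (double-bond threshold).
# A bond shorter than L2 is a definite double; between L2 and L1 it falls into
# the provisional codes 5/4/6; at or beyond L1 it is a definite single.
C-C 1.49 1.33
C-N 1.43 1.29
C-O 1.41 1.28
C-S 1.80 1.72
N-N 1.38 1.29
N-O 1.39 1.24
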