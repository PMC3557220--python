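# Per-element limits: maximum connection count (neighbours) and maximum
# valence (sum of bond orders).  Cl/Br/I are raised to 7 inside perceived
# halogen-oxoacid groups (terminal oxygen neighbours); see tables.py.
# Columns: element  max_connections  max_valence
H  1 1
C  4 4
N  4 4
O  2 2
F  1 1
P  4 5
S  4 6
CL 1 1
BR 1 1
I  1 1
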