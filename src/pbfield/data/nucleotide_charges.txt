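# Charge/radius template for the synthetic pseudo-nucleotides.
# Columns: residue  atom  charge(e)  radius(A)
# DN  backbone pseudo-nucleotide: the -1 e lives on the phosphate.
# RU  flipped-out uracil-like base residue: the -1 e is spread over the
#     base ring; phosphate and sugar are neutralized so the whole
#     residue (the base-flipping probe group) carries net -1 e.
# C   cytosine-like replacement with the same atom names and the same
#     net charge of -1 e, redistributed over the ring.
DN  P    -1.00  1.90
DN  C1'   0.00  1.70
DN  N1    0.00  1.55
RU  P     0.00  1.90
RU  C1'   0.00  1.70
RU  N1   -0.20  1.55
RU  C2    0.30  1.70
RU  O2   -0.45  1.52
RU  N3   -0.30  1.55
RU  C4    0.40  1.70
RU  O4   -0.45  1.52
RU  C5   -0.20  1.70
RU  C6   -0.10  1.70
C   P     0.00  1.90
C   C1'   0.00  1.70
C   N1   -0.25  1.55
C   C2    0.35  1.70
C   O2   -0.50  1.52
C   N3   -0.35  1.55
C   C4    0.45  1.70
C   O4   -0.40  1.52
C   C5   -0.15  1.70
C   C6   -0.15  1.70
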