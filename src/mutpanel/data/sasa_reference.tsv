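# Reference accessible surface area (A^2) of residue X in an extended
# Ala-X-Ala tripeptide, used as the denominator of relative accessibility.
# Values computed once with the package's own ideal-geometry tripeptide
# builder (phi = psi = 180, chi1 = -60) and Shrake-Rupley quadrature
# (probe 1.4 A, 4000 points), so relative accessibilities are internally
# consistent with the pipeline's SASA convention.
A	99.8
R	232.2
N	138.9
D	137.9
C	125.3
Q	172.8
E	171.2
G	72.6
H	179.7
I	159.0
L	149.5
K	187.9
M	179.4
F	191.1
P	119.1
S	112.2
T	136.2
W	229.6
Y	208.8
V	138.9
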