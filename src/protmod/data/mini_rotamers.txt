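# Miniature backbone-independent rotamer library (fixture data).
# AA prob chi1 chi2 chi3 chi4 sig1 sig2 sig3 sig4
A 1.00 0 0 0 0 0 0 0 0
S 0.48 62 0 0 0 10 0 0 0
S 0.30 -65 0 0 0 10 0 0 0
S 0.22 180 0 0 0 10 0 0 0
C 0.55 -65 0 0 0 10 0 0 0
C 0.26 -177 0 0 0 10 0 0 0
C 0.19 63 0 0 0 10 0 0 0
T 0.49 59 0 0 0 9 0 0 0
T 0.43 -61 0 0 0 9 0 0 0
T 0.08 -175 0 0 0 9 0 0 0
V 0.73 175 0 0 0 9 0 0 0
V 0.20 -60 0 0 0 9 0 0 0
V 0.07 64 0 0 0 9 0 0 0
I 0.62 -65 169 0 0 9 11 0 0
I 0.23 62 170 0 0 9 11 0 0
I 0.15 -57 -60 0 0 9 11 0 0
L 0.59 -65 175 0 0 9 11 0 0
L 0.29 -172 65 0 0 9 11 0 0
L 0.12 -85 65 0 0 9 11 0 0
D 0.51 -70 -15 0 0 9 14 0 0
D 0.31 -177 3 0 0 9 14 0 0
D 0.18 63 2 0 0 9 14 0 0
N 0.47 -68 -36 0 0 10 20 0 0
N 0.29 -177 0 0 0 10 20 0 0
N 0.24 62 -41 0 0 10 20 0 0
H 0.45 -63 -74 0 0 10 16 0 0
H 0.33 -177 64 0 0 10 16 0 0
H 0.22 62 -85 0 0 10 16 0 0
F 0.49 -65 94 0 0 9 14 0 0
F 0.33 -177 80 0 0 9 14 0 0
F 0.18 62 90 0 0 9 14 0 0
Y 0.49 -65 94 0 0 9 14 0 0
Y 0.33 -177 80 0 0 9 14 0 0
Y 0.18 62 90 0 0 9 14 0 0
W 0.40 -65 95 0 0 9 15 0 0
W 0.35 -177 -105 0 0 9 15 0 0
W 0.25 62 90 0 0 9 15 0 0
P 0.55 30 -40 0 0 7 8 0 0
P 0.45 -25 35 0 0 7 8 0 0
E 0.42 -67 -178 -3 0 9 12 15 0
E 0.33 -177 178 -2 0 9 12 15 0
E 0.25 -65 -65 -40 0 9 12 15 0
Q 0.42 -67 -178 -4 0 9 12 16 0
Q 0.33 -177 178 -2 0 9 12 16 0
Q 0.25 -65 -65 -40 0 9 12 16 0
M 0.40 -65 -177 73 0 9 12 14 0
M 0.33 -177 179 75 0 9 12 14 0
M 0.27 -65 -65 -70 0 9 12 14 0
K 0.40 -67 -179 -179 -179 9 12 13 14
K 0.35 -177 179 179 179 9 12 13 14
K 0.25 -65 -65 -179 -179 9 12 13 14
R 0.38 -67 -179 -179 -179 9 12 13 14
R 0.34 -177 179 179 85 9 12 13 14
R 0.28 -65 -65 -179 -179 9 12 13 14
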