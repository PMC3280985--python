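one_letter,three_letter,ha_ppm
A,Ala,4.32
C,Cys,4.55
D,Asp,4.64
E,Glu,4.35
F,Phe,4.62
G,Gly,3.96
H,His,4.73
I,Ile,4.17
K,Lys,4.32
L,Leu,4.34
M,Met,4.48
N,Asn,4.74
P,Pro,4.42
Q,Gln,4.34
R,Arg,4.34
S,Ser,4.47
T,Thr,4.35
V,Val,4.12
W,Trp,4.66
Y,Tyr,4.55
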