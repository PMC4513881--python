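# Random-coil 13C chemical shifts (ppm) for CA and C' (carbonyl),
# after Wishart et al. (1995) J. Biomol. NMR 5, 67-81 (GGXGG peptides,
# referenced to DSS). Cys values are for the reduced form.
aa,ca,co
A,52.5,177.8
C,58.2,174.6
D,54.2,176.3
E,56.6,176.6
F,57.7,175.8
G,45.1,174.9
H,55.0,174.1
I,61.1,176.4
K,56.2,176.6
L,55.1,177.6
M,55.4,176.3
N,53.1,175.2
P,63.3,177.3
Q,55.7,176.0
R,56.0,176.3
S,58.3,174.6
T,61.8,174.7
V,62.2,176.3
W,57.5,176.1
Y,57.9,175.9
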