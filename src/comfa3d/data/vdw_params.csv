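element,vdw_radius,vdw_epsilon
H,1.50,0.042
C,1.70,0.107
N,1.55,0.095
O,1.52,0.116
F,1.47,0.109
P,1.80,0.314
S,1.80,0.314
Cl,1.75,0.314
Br,1.85,0.434
I,1.98,0.623
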