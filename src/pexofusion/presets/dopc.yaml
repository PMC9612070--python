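# Pure DOPC monolayer.
# Units: B in k_BT; K, sigma0 in k_BT/nm^2; Js in 1/nm; P0 in k_BT/nm^3;
# xi_h, xi_f in nm; sigma is dimensionless (lateral tension / K).
B: 10.0
K: 10.0
Js: -0.1
sigma: 0.001
P0: 800.0
xi_h: 0.235
sigma0: 12.5
xi_f: 1.0
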