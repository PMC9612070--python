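# Equimolar DOPC:DOPE mixture: more negative spontaneous curvature and
# weaker, longer-ranged hydration repulsion than pure DOPC.
# Units as in dopc.yaml.
B: 10.0
K: 10.0
Js: -0.25
sigma: 0.001
P0: 60.0
xi_h: 0.37
sigma0: 12.5
xi_f: 1.0
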