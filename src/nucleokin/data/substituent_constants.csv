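substituent,sigma_p,sigma_p_plus
OCH3,-0.27,-0.78
CH3,-0.17,-0.31
H,0.00,0.00
F,0.06,-0.07
Cl,0.23,0.11
CF3,0.54,0.61
CN,0.66,0.66
NO2,0.78,0.79
NH2,,-1.30
NHCH3,,-1.81
N(CH3)2,,-1.70
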