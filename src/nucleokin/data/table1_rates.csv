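label,substituent,k_pH2,k1_pH2,k_pH1,k1_pH1,k_deuterio_pH2,k1_deuterio_pH2,k_deuterio_pH1,k1_deuterio_pH1,sigma_p,sigma_p_plus,E
7a,OCH3,5.30e-1,1.33e1,6.00e-2,1.45e1,4.90e-1,1.23e1,5.30e-2,1.30e1,-0.27,-0.78,-8.4
7b,CH3,2.78,6.95e1,2.40e-1,5.88e1,,,,,-0.17,-0.31,-7.7
7c,H,1.71e1,4.27e2,1.93,4.65e2,1.79e1,4.45e2,1.67,4.12e2,0.00,0.00,-7.2
7d,F,4.12e1,1.03e3,4.19,1.01e3,,,,,0.06,-0.07,
7e,Cl,8.46e1,2.11e3,8.54,2.06e3,,,,,0.23,0.11,-6.7
7f,CF3,1.03e3,2.57e4,1.07e2,2.58e4,,,,,0.54,0.61,-5.7
7g,CN,1.38e3,3.44e4,1.29e2,3.10e4,1.21e3,3.02e4,1.31e2,3.21e4,0.66,0.66,-5.5
7h,NO2,3.83e3,9.55e4,3.45e2,8.32e4,,,,,0.78,0.79,-5.1
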