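name,sigma_plus_C3,k_ref,E_ref,N,s_N,N_exp
3-aminothiophene,-1.30,3.37e4,-5.06,9.59,1.0,9.37
3-(methylamino)thiophene,-1.81,2.58e5,-5.06,10.47,1.0,
3-(dimethylamino)thiophene,-1.70,9.03e4,-5.06,10.02,1.0,
"1,2,3-trimethylpyrrole",,2.40e4,-5.06,9.44,1.0,
N-methylpyrrole,,1.00e2,-5.06,7.06,1.0,
N-methylindole,,3.51e3,-5.06,8.61,1.0,
indole,,5.55e2,-5.06,7.80,1.0,
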