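nucleophile_name,N_pred,E,k_exp,k_calc,ratio
3-methoxythiophene,8.29,-9.56,4.51e-1,5.37e-2,8.4
3-methylthiophene,7.34,-9.56,9.38e-2,6.03e-3,15.6
thiophene,6.72,-9.56,1.60e-2,1.46e-3,11.1
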