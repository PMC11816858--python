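culture_type,R_bg,sigma_R_bg,R_B,sigma_R_B,R_H,R_N,R_gamma
2D,9.79,0.09,1.31,0.01,0.699,3.28,5.81
spheroid,14.98,0.08,1.70,0.03,0.119,4.26,10.6
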