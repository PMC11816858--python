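cell_line,culture_type,P_kW,C_B_ppm,sigma_C_B_ppm,sigma_sys_Dtot_Gy,sigma_sys_D0_Gy
WM266-4 2D,2D,20,27.5,0.5,0.14,0.04
FM55p 2D,2D,60,9.2,2.0,0.40,0.04
HEMa-LP,2D,20,26.4,1.7,0.14,0.04
WM266-4 3D,spheroid,17,36.0,6.8,0.07,0.07
FM55p 3D,spheroid,12,47.5,4.6,0.05,0.03
WM266-4 3D,spheroid,51,36.0,6.8,0.20,0.20
FM55p 3D,spheroid,36,47.5,4.6,0.14,0.14
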