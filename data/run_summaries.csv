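run_id,lignin_gL,C_BM_min,C_BM_max,C_Glc_min,C_Glc_max,C_Xyl_min,C_Xyl_max,C_Ara_min,C_Ara_max,C_LA_max,FT_h,purity_L_pct
DSM2314_L0.000,0.0,0.03,6.09,0.00,46.21,0.00,21.81,0.00,10.44,68.85,26,98.89
DSM2314_L0.625,0.625,0.04,7.78,0.00,44.64,0.00,22.36,0.00,10.76,63.71,72,98.89
ID14-298_L0.000,0.0,0.02,4.33,0.00,46.69,0.00,21.33,0.00,10.58,69.68,28,99.51
ID14-298_L0.625,0.625,0.04,5.92,0.00,45.57,0.00,20.68,0.00,10.66,67.07,48,99.70
ID14-298_L1.250,1.25,0.07,5.29,0.00,44.58,0.00,22.75,0.00,10.95,66.00,48,99.64
ID14-301_L0.000,0.0,0.03,5.00,11.90,49.78,11.27,21.22,8.81,11.70,46.95,48,99.63
ID14-301_L0.625,0.625,0.08,4.81,7.38,47.39,7.09,21.84,7.63,10.77,50.64,48,98.93
ID14-301_L1.250,1.25,0.07,5.17,0.00,42.76,11.55,22.02,8.77,10.58,45.56,48,98.89
ID14-301_L2.500,2.5,0.06,5.31,0.00,41.82,11.16,22.43,7.07,10.55,43.75,48,98.94
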