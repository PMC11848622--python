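label,mn_kda,end_group,gamma_eq,gamma_eq_sem,k_1e3_per_s,k_sem,cdi,t10_h,t10_sem,dispersity
2-V70,2,V70,44.9,0.3,5.878,0.047,7.86,11.42,0.50,1.08
4-V70,4,V70,48.6,0.2,4.633,0.082,5.54,15.46,0.24,1.11
8-V70,8,V70,49.88,0.02,4.551,0.074,2.10,24.37,0.93,1.11
12-V70,12,V70,49.6,0.7,3.880,0.027,1.56,16.67,1.51,1.14
16-V70,16,V70,50.8,0.5,3.919,0.077,1.25,14.5,0.39,1.19
20-V70,20,V70,52.3,0.2,4.070,0.042,1.20,10.37,0.36,1.20
8-AIBN,8,AIBN,50.9,0.6,3.583,0.044,2.10,12.08,0.35,1.11
Humalog Buffer,,none,71.960,0.002,,,,,,
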