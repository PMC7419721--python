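filter,va_mean,va_sd,va_rel_printed,va_significant,cr_mean,cr_sd,cr_rel_printed,cr_significant,stereo_mean,stereo_sd,stereo_rel_printed,stereo_significant
baseline,0.02,0.04,1,False,1.44,0.32,1,False,40,16,1,False
0.8,0.12,0.10,6,True,1.49,0.41,1,False,40,17,1,False
0.6,0.29,0.10,14.5,True,1.87,0.93,1.3,False,41,17,1,False
0.4,0.48,0.16,24,True,2.44,1.08,1.7,True,48,14,1.2,False
0.1,0.54,0.09,27,True,3.64,1.59,2.5,True,46,14,1.2,False
<0.1,0.97,0.12,48.5,True,9.84,8.71,6.8,True,88,36,2.2,True
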