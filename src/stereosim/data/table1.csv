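contrast_decrement,stereo_mean,stereo_sd,relative_change_printed,significant
0,40,16,1,False
10,57,22,1.4,True
20,132,212,5.3,True
30,512,750,12.8,True
40,1780,1360,44.5,True
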