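observer,cr,baseline,balanced_cr,balanced_cr_plus25,balanced_cr_minus25
1,4.85,92.22,69.64,73.88,60.74
2,5.553,68.89,33.31,32.12,45.15
3,91.5926,4359.21,2522.58,2788,1782.59
4,2.5828,1145.63,553.14,903.56,647.12
5,4.0378,3964.91,1595.73,2087,2053.26
6,39.1606,2204.13,602.31,1054.45,881.7
7,42.4783,1482.48,1360.97,1556.76,1478.09
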