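locus,band,unit_nt
D1S1656,1q42,4
D2S441,2p14,4
D3S1358,3p21.31,4
D5S818,5q23.2,4
D7S820,7q21.11,4
D8S1179,8q24.13,4
D10S1248,10q26.3,4
D12S391,12p13.2,4
D13S317,13q31.1,4
D16S539,16q24.1,4
D18S51,18q21.33,4
D21S11,21q21.1,4
D22S1045,22q12.3,3
CSF1PO,5q33.1,4
FGA,4q31.3,4
SE33,6q14,4
TH01,11p15.5,4
TPOX,2p25.3,4
vWA,12p13.31,4
AMELO,Xp22.1-22.3/Yp11.2,0
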