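center_cm1,amplitude,fwhm_cm1
2916,1.0,30
2852,0.6,30
1645,1.0,12
1555,1.0,12
1464,0.6,12
1375,0.6,12
1234,0.6,12
1164,1.0,12
1087,0.6,12
1064,0.6,12
964,0.6,12
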