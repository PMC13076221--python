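center_cm1,amplitude,fwhm_cm1
2932,1.0,30
2900,1.0,30
2866,1.0,30
2848,1.0,30
1464,0.6,12
1375,0.6,12
1327,1.0,12
1056,1.0,12
1023,1.0,12
958,1.0,12
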