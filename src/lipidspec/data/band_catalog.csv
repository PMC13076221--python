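position_cm1,vibration,species
2932,nu_as CH2 + nu_as CH3,Chol
2923,nu_as CH2 of acyl chain,DOPC
2916,nu_as CH2,SM
2900,nu_s CH2,Chol
2866,nu_s CH2,Chol
2852,nu_s CH2 of acyl chain,DOPC-SM
2848,nu_s CH2 and CH3,Chol
1731,nu C=O ester group,DOPC
1645,C=O amide I,SM
1555,delta N-H + nu C-N amide II,SM
1464,alpha CH2 acyl chain,All
1375,beta_s CH3,All
1327,pi CH2,Chol
1234,nu_as PO2-,DOPC-SM
1174,nu C-O + nu_s C-C-O,DOPC
1164,nu C-O + nu_s C-C-O,SM
1087,nu_s PO2-,DOPC-SM
1064,nu_as C-C-O + nu C-O-H,DOPC-SM
1056,delta C-H ring,Chol
1023,beta C-H in plane,Chol
964,nu_as N+(CH3)3 + beta C=C,DOPC-SM
958,beta =C-H,Chol
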