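conformation,site,shift_ppm
random_coil,Ala Hbeta,1.3
random_coil,Ala Halpha,4.1
random_coil,Ala HN,8.1
random_coil,Gly Halpha1,3.5
random_coil,Gly Halpha2,4.1
random_coil,Gly HN,8.1
silkII,Ala Hbeta,1.0
silkII,Ala Halpha,5.0
silkII,Ala HN,8.7
silkII,Gly Halpha1,3.9
silkII,Gly Halpha2,4.6
silkII,Gly HN,8.7
silkI*,Ala Hbeta,1.5
silkI*,Ala Halpha,4.3
silkI*,Ala HN,7.6
silkI*,Gly Halpha1,3.8
silkI*,Gly Halpha2,3.1
silkI*,Gly HN,8.8
silkI*,Ser Halpha,5.1
glyc,Glyc CH2,3.4
glyc,Glyc CH,3.4
glyc,Glyc OH,4.4
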