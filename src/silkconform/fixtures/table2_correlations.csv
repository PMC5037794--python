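film,block,site_a,site_b,label
SF,random_coil,Ala Hbeta,Ala Halpha,Ala Hbeta - Ala Halpha/Gly Halpha2
SF,random_coil,Ala Hbeta,Gly Halpha1,Ala Hbeta - Gly Halpha1
SF,random_coil,Ala Hbeta,Ala HN,Ala Hbeta - Ala HN/Gly HN
SF,random_coil,Gly Halpha1,Ala Halpha,Gly Halpha1 - Ala Halpha/Gly Halpha2
SF,random_coil,Gly Halpha1,Ala HN,Gly Halpha1 - Ala HN/Gly HN
SF,random_coil,Ala Halpha,Ala HN,Ala Halpha/Gly Halpha2 - Ala HN/Gly HN
SF,silkII,Ala Hbeta,Gly Halpha2,Ala Hbeta - Gly Halpha2
SF,silkII,Ala Hbeta,Ala Halpha,Ala Hbeta - Ala Halpha
SF,silkII,Gly Halpha1,Gly Halpha2,Gly Halpha1 - Gly Halpha2
SF,silkII,Gly Halpha1,Ala Halpha,Gly Halpha1 - Ala Halpha
SF,silkII,Gly Halpha1,Gly HN,Gly Halpha1 - Gly HN/Ala HN
SF,silkII,Ala Halpha,Gly Halpha2,Ala Halpha - Gly Halpha2
SF,silkII,Gly Halpha2,Gly HN,Gly Halpha2 - Gly HN/Ala HN
SF,silkII,Ala Halpha,Gly HN,Ala Halpha - Gly HN/Ala HN
glyc_blend,random_coil,Ala Hbeta,Ala Halpha,Ala Hbeta - Ala Halpha/Gly Halpha2
glyc_blend,random_coil,Ala Hbeta,Gly Halpha1,Ala Hbeta - Gly Halpha1
glyc_blend,random_coil,Gly Halpha1,Ala Halpha,Gly Halpha1 - Ala Halpha/Gly Halpha2
glyc_blend,random_coil,Ala Halpha,Ala HN,Ala Halpha - Ala HN/Gly HN
glyc_blend,silkI*,Ala Hbeta,Gly Halpha2,Ala Hbeta - Gly Halpha2
glyc_blend,silkI*,Ala Hbeta,Gly Halpha1,Ala Hbeta - Gly Halpha1
glyc_blend,silkI*,Ala Hbeta,Ala Halpha,Ala Hbeta - Ala Halpha
glyc_blend,silkI*,Ala Hbeta,Ala HN,Ala Hbeta - Ala HN
glyc_blend,silkI*,Gly Halpha2,Ala Halpha,Gly Halpha2 - Ala Halpha
glyc_blend,silkI*,Gly Halpha2,Ala HN,Gly Halpha2 - Ala HN
glyc_blend,silkI*,Gly Halpha2,Gly HN,Gly Halpha2 - Gly HN
glyc_blend,silkI*,Gly Halpha1,Ala Halpha,Gly Halpha1 - Ala Halpha
glyc_blend,silkI*,Gly Halpha1,Ala HN,Gly Halpha1 - Ala HN
glyc_blend,silkI*,Gly Halpha1,Gly HN,Gly Halpha1 - Gly HN
glyc_blend,silkI*,Ser Halpha,Gly HN,Ser Halpha - Gly HN
glyc_blend,silkI*,Ala Halpha,Gly HN,Ala Halpha - Gly HN
glyc_blend,glyc-silkI*,Glyc CH2,Ala Hbeta,Glyc (CH2) - Ala Hbeta
glyc_blend,glyc-silkI*,Glyc CH2,Gly Halpha1,Glyc (CH2) - Gly Halpha1
glyc_blend,glyc-silkI*,Glyc CH2,Ser Halpha,Glyc (CH2) - Ser Halpha
glyc_blend,glyc-silkI*,Glyc OH,Gly Halpha1,Glyc (OH) - Gly Halpha1
glyc_blend,glyc-silkI*,Glyc OH,Ser Halpha,Glyc (OH) - Ser Halpha
glyc_blend,glyc-silkI*,Glyc OH,Ala HN,Glyc (OH) - Ala HN
glyc_blend,glyc-silkI*,Glyc OH,Gly HN,Glyc (OH) - Gly HN
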