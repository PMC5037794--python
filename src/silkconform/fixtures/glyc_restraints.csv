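group_a,group_b,upper_bound
Glyc CH2,Ala Hbeta,4.0
Glyc CH2,Gly Halpha1,4.0
Glyc CH2,Ser Halpha,4.0
Glyc OH,Ser Halpha,4.0
Glyc OH,Ala HN,4.0
Glyc OH,Gly HN,4.0
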