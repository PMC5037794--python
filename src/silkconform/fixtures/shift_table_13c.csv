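conformation,site,shift_ppm
random_coil,Ala Cbeta,16.7
random_coil,Ala Calpha,50.0
random_coil,Ala CO,175.5
random_coil,Gly Calpha,42.6
random_coil,Gly CO,171.3
silkII,Ala Cbeta A,19.6
silkII,Ala Cbeta B,21.7
silkII,Ala Calpha,49.2
silkII,Ala CO,172.6
silkII,Gly Calpha,43.0
silkII,Gly CO,169.1
silkI*,Ala Cbeta,16.5
silkI*,Ala Calpha,51.4
silkI*,Ala CO,177.0
silkI*,Gly Calpha,43.8
silkI*,Gly CO,170.7
silkI*,Ser Cbeta,60.7
glyc,Glyc CH2,62.9
glyc,Glyc CH,72.3
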