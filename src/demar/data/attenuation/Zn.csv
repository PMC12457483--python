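energy_keV,mu_over_rho_cm2_g
5,212.065
6,129.692
8,59.7412
9.659,35.987
9.659,261.589
10,236.977
15,74.7366
20,33.014
30,10.5067
40,4.71519
50,2.56685
60,1.58512
80,0.774498
100,0.470677
150,0.227929
200,0.15872
300,0.112252
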