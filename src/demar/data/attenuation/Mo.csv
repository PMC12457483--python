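energy_keV,mu_over_rho_cm2_g
5,66.3732
6,44.4982
8,23.7099
10,14.5768
15,6.07063
20,3.29862
20,19.9178
20,19.9178
30,7.47312
40,3.76795
50,2.24081
60,1.48268
80,0.797783
100,0.512918
150,0.258793
200,0.177249
300,0.119105
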