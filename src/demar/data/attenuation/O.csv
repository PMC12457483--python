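energy_keV,mu_over_rho_cm2_g
5,43.183
6,25.5299
8,11.1941
10,5.95191
15,1.96649
20,0.957655
30,0.417976
40,0.277676
50,0.223228
60,0.196204
80,0.169358
100,0.155659
150,0.135845
200,0.123379
300,0.106706
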