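energy_keV,mu_over_rho_cm2_g
5,27.1575
6,16.1322
8,7.14936
10,3.85115
15,1.33224
20,0.690093
30,0.34305
40,0.250684
50,0.213463
60,0.194035
80,0.173077
100,0.161257
150,0.142372
200,0.129728
300,0.112413
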