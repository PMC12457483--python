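energy_keV,mu_over_rho_cm2_g
5,15.9139
6,9.54357
8,4.31178
10,2.37272
15,0.875757
20,0.488287
30,0.27494
40,0.216076
50,0.191147
60,0.177354
80,0.161174
100,0.151343
150,0.134447
200,0.122715
300,0.106437
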