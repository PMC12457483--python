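energy_keV,mu_over_rho_cm2_g
5,0.4116
6,0.4045
8,0.3963
10,0.3854
15,0.3764
20,0.3695
30,0.357
40,0.3458
50,0.3355
60,0.326
80,0.3091
100,0.2944
150,0.2651
200,0.2429
300,0.2112
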