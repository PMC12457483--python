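energy_keV,mu_over_rho_cm2_g
5,189.9
6,115.6
8,52.55
8.979,38.29
8.979,278.4
10,215.9
15,74.05
20,33.79
30,10.92
40,4.862
50,2.613
60,1.593
80,0.763
100,0.4584
150,0.2217
200,0.1559
300,0.1119
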