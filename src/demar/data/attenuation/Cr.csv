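energy_keV,mu_over_rho_cm2_g
5,118.763
5.989,73.0225
5.989,619.337
6,616.051
8,267.583
10,140.178
15,43.3729
20,18.9278
30,5.95338
40,2.67368
50,1.47168
60,0.927008
80,0.480191
100,0.313245
150,0.177716
200,0.136606
300,0.105509
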