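energy_keV,mu_over_rho_cm2_g
5,81.3757
6,54.5428
8,29.0431
10,17.8402
15,7.40687
20,4.0073
24.35,2.65299
24.35,15.1267
30,9.13293
40,4.58729
50,2.71434
60,1.785
80,0.946376
100,0.598292
150,0.289547
200,0.19183
300,0.123836
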