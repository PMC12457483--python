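energy_keV,mu_over_rho_cm2_g
5,26.7723
6,16.0016
8,7.15644
10,3.8788
15,1.35004
20,0.697241
30,0.340786
40,0.245119
50,0.206555
60,0.186545
80,0.165257
100,0.153532
150,0.135173
200,0.123061
300,0.106574
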