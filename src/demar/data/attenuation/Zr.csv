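energy_keV,mu_over_rho_cm2_g
5,59.3426
6,39.7908
8,21.2102
10,13.0469
15,5.44381
17.998,3.69893
17.998,23.1395
20,17.9065
30,6.72846
40,3.40007
50,2.02797
60,1.34659
80,0.730643
100,0.474141
150,0.244552
200,0.170296
300,0.116622
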