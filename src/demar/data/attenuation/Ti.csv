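energy_keV,mu_over_rho_cm2_g
5,821.249
6,484.078
8,210.281
10,110.177
15,34.1155
20,14.908
30,4.71254
40,2.13454
50,1.1891
60,0.760219
80,0.407441
100,0.274893
150,0.165536
200,0.131064
300,0.103529
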