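energy_keV,mu_over_rho_cm2_g
5,162.231
6,99.2311
7.709,50.5255
7.709,397.922
8,357.664
10,188.177
15,58.6547
20,25.7088
30,8.10901
40,3.62888
50,1.97936
60,1.2297
80,0.613742
100,0.38381
150,0.19951
200,0.14582
300,0.107966
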