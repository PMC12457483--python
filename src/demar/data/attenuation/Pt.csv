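energy_keV,mu_over_rho_cm2_g
5,713.488
6,444.194
8,210.329
10,117.81
11.564,80.7898
11.564,322.699
15,162.029
20,75.6752
30,25.9342
40,12.1723
50,6.7965
60,4.2403
78.395,2.14768
78.395,9.42995
80,8.94112
100,4.98867
150,1.76309
200,0.868407
300,0.347135
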