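energy_keV,mu_over_rho_cm2_g
5,759.084
6,472.577
8,223.764
10,125.33
12.284,73.4753
12.284,293.444
15,172.897
20,80.7456
30,27.6654
40,12.9798
50,7.2434
60,4.51584
80,2.16982
83.102,1.97265
83.102,8.63123
100,5.31837
150,1.87505
200,0.920374
300,0.364678
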