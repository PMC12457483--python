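energy_keV,mu_over_rho_cm2_g
5,87.005
6,58.3125
8,31.0456
10,19.0664
15,7.91016
20,4.27516
25.514,2.5661
25.514,14.3613
30,9.7072
40,4.87169
50,2.87944
60,1.89101
80,0.999281
100,0.629321
150,0.301583
200,0.198169
300,0.126607
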