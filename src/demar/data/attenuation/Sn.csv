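energy_keV,mu_over_rho_cm2_g
5,95.7544
6,64.1691
8,34.1531
10,20.9663
15,8.68555
20,4.68445
29.2,2.12113
29.2,11.3766
30,10.657
40,5.3386
50,3.14774
60,2.06102
80,1.08114
100,0.675011
150,0.316219
200,0.203764
300,0.126905
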