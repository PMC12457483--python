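energy_keV,mu_over_rho_cm2_g
5,737.058
6,458.866
8,217.274
10,121.698
11.919,77.1565
11.919,308.165
15,167.631
20,78.2892
30,26.8271
40,12.5891
50,7.02744
60,4.3829
80,2.10815
80.725,2.06106
80.725,9.03268
100,5.15904
150,1.82124
200,0.895612
300,0.356549
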