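energy_keV,mu_over_rho_cm2_g
5,695.865
6,410.189
8,178.208
10,93.3925
15,28.9466
20,12.6719
30,4.03224
40,1.84675
50,1.04457
60,0.680132
80,0.379304
100,0.265443
150,0.169544
200,0.137881
300,0.111043
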