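# Collisional (electronic) mass stopping power of liquid water for electrons.
# Coarse grid transcribed from the standard NIST ESTAR tabulation (ICRU 37
# methodology); intermediate energies are obtained by log-log interpolation.
# energy_kev, s_col_mev_cm2_per_g
10,22.56
20,13.17
30,9.653
50,6.603
70,5.294
100,4.115
200,2.793
300,2.355
400,2.148
500,2.034
700,1.911
1000,1.849
1500,1.822
2000,1.824
3000,1.846
4000,1.868
5000,1.892
7000,1.931
10000,1.968
15000,2.014
20000,2.046
30000,2.089
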