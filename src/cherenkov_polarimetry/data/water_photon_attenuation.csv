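# Total mass attenuation coefficient (without coherent scattering) of liquid
# water for photons.  Coarse grid transcribed from the standard NIST XCOM
# tabulation; intermediate energies are obtained by log-log interpolation.
# energy_kev, mu_over_rho_cm2_per_g
100,0.1707
150,0.1505
200,0.1370
300,0.1186
400,0.1061
500,0.0969
600,0.0896
800,0.0786
1000,0.0707
1250,0.0632
1500,0.0575
2000,0.0494
3000,0.0397
4000,0.0340
5000,0.0303
6000,0.0277
8000,0.0243
10000,0.0222
15000,0.0194
20000,0.0181
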