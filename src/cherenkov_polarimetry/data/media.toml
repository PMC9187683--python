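# Optical/transport constants of the dielectric media used in Cherenkov
# dosimetry.  Refractive indices are the values conventionally used for the
# visible band (dispersion is neglected); radiation lengths are the standard
# tabulated values used by the Highland multiple-scattering formula.

[water]
refractive_index = 1.33
density = 1.0            # g/cm^3
radiation_length = 36.08 # g/cm^2

[polyvinyl_toluene]
refractive_index = 1.58
density = 1.032
radiation_length = 43.79
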