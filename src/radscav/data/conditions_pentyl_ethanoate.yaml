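# Pentyl ethanoate (lipid-mimetic ester solvent) at 298.15 K.
# Viscosity from standard solvent tables at 298.15 K.
# Stokes radii: solute from its molar volume (~5.0 A for the pyrrolo-
# quinoxaline ester 3a), 2.0 A for the hydroxyl radical.
medium: pentyl ethanoate
temperature_K: 298.15
viscosity_Pa_s: 8.62e-4
solute_radius_m: 5.0e-10
radical_radius_m: 2.0e-10
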