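# Gas phase, 298.15 K: no diffusion correction (k_app = k_act exactly).
medium: gas
temperature_K: 298.15
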